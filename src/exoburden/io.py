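"""Readers and writers for every external format the pipeline touches.

Formats
-------
* variant tables: a minimal VCF 4.2 subset (via :mod:`cyvcf2`) and a compact
  TSV dialect carrying one row per variant with an explicit carrier list;
* transcript models: GTF (via :mod:`gffutils`) and BED12;
* kinship, sample-registry, genotype-matrix and database-count TSVs;
* burden-result / QQ-coordinate TSVs and run-metadata JSON.

Coordinates are 1-based inclusive internally; the BED12 reader converts from
0-based half-open at the boundary. Multi-allelic VCF records are decomposed
into biallelic variants at read time. Reals are serialized to 12 significant
digits so that write -> read round-trips are lossless at that precision.
"""

from __future__ import annotations

import csv
import json
import math
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import (
    AnnotatedVariant,
    CalibrationResult,
    Consequence,
    DatabaseCount,
    GeneBurdenResult,
    GenotypeCall,
    KinshipPair,
    CohortDesign,
    Sample,
    TranscriptModel,
    ValidationError,
    VariantClass,
)


class ParseError(ValueError):
    """A malformed record in an input file; message names file, line and field."""


_G = "%.12g"  # serialization precision for reals


def _fmt(x: float) -> str:
    return _G % x


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

#: Fixed (non-AF) INFO keys of the VCF dialect.
VCF_INFO_KEYS = ("GENE", "TX", "CSQ", "QD")

_TSV_FIXED_COLS = [
    "variant_id",
    "gene",
    "transcript_id",
    "consequence",
    "pred_sift",
    "pred_pp2",
    "pred_mt",
    "mean_dp",
    "mean_qd",
    "mean_qual",
    "cds_ptc_pos",
    "carriers",
]


def read_variant_table(path: str | os.PathLike, dialect: str) -> list[AnnotatedVariant]:
    """Read a variant table into validated :class:`AnnotatedVariant` records.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {"vcf", "tsv"}
        ``"vcf"`` expects the minimal VCF 4.2 subset (INFO keys GENE, TX, CSQ,
        QD, PRED_* and AF_INT_* / AF_EXT_*; FORMAT GT:DP:AD:GQ); ``"tsv"``
        expects one row per variant with an explicit carrier-list column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _info_get(variant, key: str, line_no: int):
    val = variant.INFO.get(key)
    if val is None:
        raise ParseError(f"line {line_no}: missing mandatory INFO key {key}")
    return val


def _pick_alt(val, alt_index: int):
    """Select the per-alt element of a possibly comma-joined INFO value."""
    if isinstance(val, str) and "," in val:
        return val.split(",")[alt_index]
    if isinstance(val, tuple):
        return val[alt_index]
    return val


def _read_vcf(path: Path) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[AnnotatedVariant] = []
    # data line numbers for error reporting: count header lines first
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break
    for rec_idx, v in enumerate(vcf):
        line_no = n_header + rec_idx + 1
        alts = v.ALT or []
        ad = v.format("AD")
        dp = v.format("DP")
        gq = v.format("GQ")
        if dp is not None:
            dp = np.asarray(dp).reshape(len(samples), -1)[:, 0]
        if gq is not None:
            gq = np.asarray(gq).reshape(len(samples), -1)[:, 0]
        for alt_index, alt in enumerate(alts):
            gene = str(_info_get(v, "GENE", line_no))
            tx = str(_info_get(v, "TX", line_no))
            csq = str(_pick_alt(_info_get(v, "CSQ", line_no), alt_index))
            qd = float(_pick_alt(_info_get(v, "QD", line_no), alt_index))
            flags = None
            pred = [v.INFO.get(k) for k in ("PRED_SIFT", "PRED_PP2", "PRED_MT")]
            if all(p is not None for p in pred):
                flags = tuple(bool(int(p)) for p in pred)  # type: ignore[arg-type]
            ptc = v.INFO.get("CDS_PTC")
            internal: dict[str, float] = {}
            external: dict[str, float] = {}
            for key, val in dict(v.INFO).items():
                if key.startswith("AF_INT_"):
                    internal[key[len("AF_INT_"):]] = float(_pick_alt(val, alt_index))
                elif key.startswith("AF_EXT_"):
                    external[key[len("AF_EXT_"):]] = float(_pick_alt(val, alt_index))
            genotypes = []
            alt_allele_number = alt_index + 1
            for si, gt in enumerate(v.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                ac = sum(1 for a in alleles if a == alt_allele_number)
                s_dp = int(dp[si]) if dp is not None and dp[si] >= 0 else 0
                s_gq = float(gq[si]) if gq is not None and gq[si] >= 0 else 0.0
                alt_frac = None
                if ad is not None and s_dp > 0:
                    row = ad[si]
                    if alt_allele_number < len(row) and row[alt_allele_number] >= 0:
                        alt_frac = float(row[alt_allele_number]) / s_dp
                if ac > 0 and alt_frac is None:
                    alt_frac = 0.0
                genotypes.append(
                    GenotypeCall(samples[si], ac, s_dp, alt_frac, s_gq)
                )
            try:
                out.append(
                    AnnotatedVariant(
                        variant_id=f"{v.CHROM}:{v.POS}:{v.REF}:{alt}",
                        gene=gene,
                        transcript_id=tx,
                        consequence=Consequence(csq),
                        predictor_flags=flags,  # type: ignore[arg-type]
                        mean_QD=qd,
                        mean_QUAL=float(v.QUAL if v.QUAL is not None else 0.0),
                        mean_DP=float(_pick_alt(_info_get(v, "DP", line_no), alt_index)),
                        internal_af_by_cohort=internal,
                        external_af_by_db=external,
                        genotypes=genotypes,
                        cds_ptc_position=int(ptc) if ptc is not None else None,
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return out


def _read_variant_tsv(path: Path) -> list[AnnotatedVariant]:
    out: list[AnnotatedVariant] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return out
        missing = [c for c in _TSV_FIXED_COLS if c not in reader.fieldnames]
        if missing:
            raise ParseError(f"missing mandatory column(s): {', '.join(missing)}")
        af_int_cols = [c for c in reader.fieldnames if c.startswith("af_int_")]
        af_ext_cols = [c for c in reader.fieldnames if c.startswith("af_ext_")]
        for line_no, row in enumerate(reader, start=2):
            try:
                flags = None
                preds = [row["pred_sift"], row["pred_pp2"], row["pred_mt"]]
                if all(p not in ("", None) for p in preds):
                    flags = tuple(bool(int(p)) for p in preds)
                genotypes = []
                if row["carriers"]:
                    for entry in row["carriers"].split(";"):
                        sid, ac, gdp, frac, ggq = entry.split(":")
                        genotypes.append(
                            GenotypeCall(sid, int(ac), int(gdp), float(frac), float(ggq))
                        )
                out.append(
                    AnnotatedVariant(
                        variant_id=row["variant_id"],
                        gene=row["gene"],
                        transcript_id=row["transcript_id"],
                        consequence=Consequence(row["consequence"]),
                        predictor_flags=flags,  # type: ignore[arg-type]
                        mean_QD=float(row["mean_qd"]),
                        mean_QUAL=float(row["mean_qual"]),
                        mean_DP=float(row["mean_dp"]),
                        internal_af_by_cohort={
                            c[len("af_int_"):]: float(row[c])
                            for c in af_int_cols
                            if row[c] != ""
                        },
                        external_af_by_db={
                            c[len("af_ext_"):]: float(row[c])
                            for c in af_ext_cols
                            if row[c] != ""
                        },
                        genotypes=genotypes,
                        cds_ptc_position=(
                            int(row["cds_ptc_pos"]) if row["cds_ptc_pos"] else None
                        ),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return out


def write_variant_tsv(variants: Sequence[AnnotatedVariant], path: str | os.PathLike) -> None:
    """Write variants in the compact TSV dialect (carriers listed explicitly)."""
    int_labels = sorted({l for v in variants for l in v.internal_af_by_cohort})
    ext_labels = sorted({l for v in variants for l in v.external_af_by_db})
    cols = _TSV_FIXED_COLS + [f"af_int_{l}" for l in int_labels] + [
        f"af_ext_{l}" for l in ext_labels
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for v in variants:
            carriers = ";".join(
                f"{g.sample_id}:{g.allele_count}:{g.depth_DP}:"
                f"{_fmt(g.alt_fraction if g.alt_fraction is not None else 0)}:"
                f"{_fmt(g.genotype_quality_GQ)}"
                for g in v.genotypes
                if g.allele_count > 0
            )
            row = [
                v.variant_id,
                v.gene,
                v.transcript_id,
                v.consequence.value,
                *(
                    ["", "", ""]
                    if v.predictor_flags is None
                    else [int(f) for f in v.predictor_flags]
                ),
                _fmt(v.mean_DP),
                _fmt(v.mean_QD),
                _fmt(v.mean_QUAL),
                "" if v.cds_ptc_position is None else v.cds_ptc_position,
                carriers,
            ]
            row += [_fmt(v.internal_af_by_cohort.get(l, 0.0)) for l in int_labels]
            row += [_fmt(v.external_af_by_db.get(l, 0.0)) for l in ext_labels]
            w.writerow(row)


def write_variant_vcf(
    variants: Sequence[AnnotatedVariant],
    path: str | os.PathLike,
    sample_order: Sequence[str],
) -> None:
    """Write variants in the minimal VCF 4.2 dialect.

    Every registered sample gets a genotype column; samples absent from a
    variant's genotype list are emitted as homozygous reference.
    """
    int_labels = sorted({l for v in variants for l in v.internal_af_by_cohort})
    ext_labels = sorted({l for v in variants for l in v.external_af_by_db})
    lines = ["##fileformat=VCFv4.2"]
    chroms = sorted({v.variant_id.split(":")[0] for v in variants})
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=TX,Number=1,Type=String,Description="Canonical transcript">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Mean quality by depth">',
        '##INFO=<ID=DP,Number=1,Type=Float,Description="Site mean read depth">',
        '##INFO=<ID=CDS_PTC,Number=1,Type=Integer,Description="CDS coordinate of induced PTC">',
        '##INFO=<ID=PRED_SIFT,Number=1,Type=Integer,Description="Deleterious by predictor 1">',
        '##INFO=<ID=PRED_PP2,Number=1,Type=Integer,Description="Deleterious by predictor 2">',
        '##INFO=<ID=PRED_MT,Number=1,Type=Integer,Description="Deleterious by predictor 3">',
    ]
    for l in int_labels:
        lines.append(
            f'##INFO=<ID=AF_INT_{l},Number=1,Type=Float,Description="Internal AF ({l})">'
        )
    for l in ext_labels:
        lines.append(
            f'##INFO=<ID=AF_EXT_{l},Number=1,Type=Float,Description="External AF ({l})">'
        )
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += list(sample_order)
    lines.append("\t".join(header))

    def sort_key(v: AnnotatedVariant):
        chrom, pos, ref, alt = v.variant_id.split(":")
        return (chrom, int(pos), ref, alt)

    for v in sorted(variants, key=sort_key):
        chrom, pos, ref, alt = v.variant_id.split(":")
        info = [
            f"GENE={v.gene}",
            f"TX={v.transcript_id}",
            f"CSQ={v.consequence.value}",
            f"QD={_fmt(v.mean_QD)}",
            f"DP={_fmt(v.mean_DP)}",
        ]
        if v.cds_ptc_position is not None:
            info.append(f"CDS_PTC={v.cds_ptc_position}")
        if v.predictor_flags is not None:
            s, p, m = v.predictor_flags
            info += [f"PRED_SIFT={int(s)}", f"PRED_PP2={int(p)}", f"PRED_MT={int(m)}"]
        for l in int_labels:
            info.append(f"AF_INT_{l}={_fmt(v.internal_af_by_cohort.get(l, 0.0))}")
        for l in ext_labels:
            info.append(f"AF_EXT_{l}={_fmt(v.external_af_by_db.get(l, 0.0))}")
        by_id = {g.sample_id: g for g in v.genotypes}
        cols = [chrom, pos, ".", ref, alt, _fmt(v.mean_QUAL), "PASS", ";".join(info), "GT:DP:AD:GQ"]
        for sid in sample_order:
            g = by_id.get(sid)
            if g is None or g.allele_count == 0:
                dp = g.depth_DP if g is not None else 30
                gq = int(round(g.genotype_quality_GQ)) if g is not None else 60
                cols.append(f"0/0:{dp}:{dp},0:{gq}")
            else:
                gt = "0/1" if g.allele_count == 1 else "1/1"
                ad_alt = int(round((g.alt_fraction or 0.0) * g.depth_DP))
                ad_ref = g.depth_DP - ad_alt
                cols.append(
                    f"{gt}:{g.depth_DP}:{ad_ref},{ad_alt}:{int(round(g.genotype_quality_GQ))}"
                )
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------


def read_transcript_models(
    path: str | os.PathLike, dialect: str
) -> dict[str, TranscriptModel]:
    """Read transcript models from GTF or BED12 into transcription-ordered exons."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gtf(path: Path) -> dict[str, TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    strands: dict[str, str] = {}
    for feat in db.all_features():
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        strands[tid] = feat.strand
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append((feat.start, feat.end))
    out = {}
    for tid, ex in exons.items():
        if tid not in cds:
            raise ParseError(f"transcript {tid}: no CDS features present")
        strand = strands[tid]
        ex_sorted = sorted(ex)
        if strand == "-":
            ex_sorted = ex_sorted[::-1]
        lo = min(s for s, _ in cds[tid])
        hi = max(e for _, e in cds[tid])
        cds_start, cds_end = (lo, hi) if strand == "+" else (hi, lo)
        try:
            out[tid] = TranscriptModel(tid, strand, ex_sorted, cds_start, cds_end)
        except ValidationError as exc:
            raise ParseError(f"transcript {tid}: {exc}") from exc
    return out


def _read_bed12(path: Path) -> dict[str, TranscriptModel]:
    out = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"line {line_no}: BED12 requires 12 fields")
            chrom_start = int(f[1])
            tid, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"line {line_no}: block count mismatch")
            # 0-based half-open -> 1-based inclusive
            exons = [
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            if strand == "-":
                exons = exons[::-1]
            lo, hi = thick_start + 1, thick_end
            cds_start, cds_end = (lo, hi) if strand == "+" else (hi, lo)
            try:
                out[tid] = TranscriptModel(tid, strand, exons, cds_start, cds_end)
            except ValidationError as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return out


def write_transcript_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | os.PathLike,
    chrom: str = "1",
    gene_of: Optional[dict[str, str]] = None,
) -> None:
    """Write transcripts as GTF exon + CDS features."""
    lines = []
    for t in transcripts:
        gene = (gene_of or {}).get(t.transcript_id, t.transcript_id)
        attrs = f'gene_id "{gene}"; transcript_id "{t.transcript_id}";'
        lo = min(t.cds_start, t.cds_end)
        hi = max(t.cds_start, t.cds_end)
        for start, end in sorted(t.exons):
            lines.append(
                f"{chrom}\ttoy\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}"
            )
            cs, ce = max(start, lo), min(end, hi)
            if cs <= ce:
                lines.append(
                    f"{chrom}\ttoy\tCDS\t{cs}\t{ce}\t.\t{t.strand}\t0\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_transcript_bed12(
    transcripts: Iterable[TranscriptModel], path: str | os.PathLike, chrom: str = "1"
) -> None:
    """Write transcripts as BED12 (0-based half-open, blocks in genomic order)."""
    lines = []
    for t in transcripts:
        ex = sorted(t.exons)
        tx_start = ex[0][0] - 1
        tx_end = ex[-1][1]
        lo = min(t.cds_start, t.cds_end)
        hi = max(t.cds_start, t.cds_end)
        sizes = ",".join(str(e - s + 1) for s, e in ex)
        starts = ",".join(str(s - 1 - tx_start) for s, _ in ex)
        lines.append(
            "\t".join(
                [
                    chrom,
                    str(tx_start),
                    str(tx_end),
                    t.transcript_id,
                    "0",
                    t.strand,
                    str(lo - 1),
                    str(hi),
                    "0",
                    str(len(ex)),
                    sizes,
                    starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cohort registry / kinship / genotype matrix / database counts
# ---------------------------------------------------------------------------


def read_cohort_tsv(path: str | os.PathLike) -> CohortDesign:
    """Read the sample registry (sample_id, status, sex, cohort, mean_coding_depth)."""
    samples = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line_no, row in enumerate(reader, start=2):
            try:
                samples.append(
                    Sample(
                        row["sample_id"],
                        row["status"],
                        row.get("sex", "F") or "F",
                        row.get("cohort", "") or "",
                        float(row["mean_coding_depth"])
                        if row.get("mean_coding_depth")
                        else None,
                    )
                )
            except (KeyError, ValueError, ValidationError) as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return CohortDesign(samples)


def write_cohort_tsv(cohort: CohortDesign, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "status", "sex", "cohort", "mean_coding_depth"])
        for s in cohort.samples:
            w.writerow(
                [
                    s.sample_id,
                    s.status,
                    s.sex,
                    s.cohort_label,
                    "" if s.mean_coding_depth is None else _fmt(s.mean_coding_depth),
                ]
            )


def read_kinship_tsv(path: str | os.PathLike) -> list[KinshipPair]:
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line_no, row in enumerate(reader, start=2):
            try:
                pairs.append(
                    KinshipPair(row["sample_a"], row["sample_b"], float(row["kinship"]))
                )
            except (KeyError, ValueError, ValidationError) as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return pairs


def write_kinship_tsv(pairs: Iterable[KinshipPair], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_a", "sample_b", "kinship"])
        for p in pairs:
            w.writerow([p.sample_a, p.sample_b, _fmt(p.kinship_coefficient)])


def read_genotype_matrix_tsv(
    path: str | os.PathLike,
) -> tuple[list[str], np.ndarray]:
    """Read a samples x markers allele-count matrix; first column = sample_id."""
    ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ParseError("empty genotype matrix")
        for line_no, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            ids.append(f[0])
            try:
                rows.append([int(x) for x in f[1:]])
            except ValueError as exc:
                raise ParseError(f"line {line_no}: non-integer allele count") from exc
    return ids, np.asarray(rows, dtype=np.int8)


def write_genotype_matrix_tsv(
    sample_ids: Sequence[str], matrix: np.ndarray, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        n_markers = matrix.shape[1]
        fh.write("sample_id\t" + "\t".join(f"m{j}" for j in range(n_markers)) + "\n")
        for sid, row in zip(sample_ids, matrix):
            fh.write(sid + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_database_counts_tsv(path: str | os.PathLike) -> list[DatabaseCount]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line_no, row in enumerate(reader, start=2):
            try:
                by_sex = None
                if row.get("k_female") not in ("", None) and row.get("k_male") not in ("", None):
                    by_sex = (int(row["k_female"]), int(row["k_male"]))
                out.append(
                    DatabaseCount(
                        row["source"], int(row["carriers"]), int(row["n"]), by_sex
                    )
                )
            except (KeyError, ValueError, ValidationError) as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return out


def write_database_counts_tsv(
    counts: Iterable[DatabaseCount], path: str | os.PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "carriers", "n", "k_female", "k_male"])
        for c in counts:
            kf, km = ("", "") if c.carriers_by_sex is None else c.carriers_by_sex
            w.writerow([c.source_label, c.carriers, c.denominator, kf, km])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(
    results: Sequence[GeneBurdenResult],
    calibration: Optional[Sequence[CalibrationResult]],
    path_prefix: str | os.PathLike,
    metadata: Optional[dict] = None,
) -> dict[str, Path]:
    """Write burden results, QQ coordinates and run metadata.

    Emits ``<prefix>.burden.tsv`` (sorted ascending p, ties broken by gene
    symbol), ``<prefix>.qq.tsv`` and ``<prefix>.meta.json``; returns the paths.
    """
    if not results:
        raise ValueError("results must be non-empty")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    burden_path = prefix.with_suffix(prefix.suffix + ".burden.tsv")
    qq_path = prefix.with_suffix(prefix.suffix + ".qq.tsv")
    meta_path = prefix.with_suffix(prefix.suffix + ".meta.json")

    ordered = sorted(results, key=lambda r: (r.p_value, r.gene, r.variant_class.value))
    with open(burden_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "class", "a", "b", "c", "d", "p", "significant"])
        for r in ordered:
            w.writerow(
                [
                    r.gene,
                    r.variant_class.value,
                    r.case_carriers,
                    r.case_noncarriers,
                    r.control_carriers,
                    r.control_noncarriers,
                    _fmt(r.p_value),
                    int(r.exome_wide_significant),
                ]
            )

    if calibration:
        with open(qq_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["class", "rank", "expected_neglog10_p", "observed_neglog10_p"])
            for cal in calibration:
                for rank, (e, o) in enumerate(
                    zip(cal.expected_p, cal.observed_p), start=1
                ):
                    w.writerow(
                        [
                            cal.variant_class.value,
                            rank,
                            _fmt(-math.log10(e)),
                            _fmt(-math.log10(o)),
                        ]
                    )

    meta = dict(metadata or {})
    if calibration:
        meta["lambda"] = {
            c.variant_class.value: c.lambda_inflation for c in calibration
        }
        meta["n_excluded_from_lambda"] = {
            c.variant_class.value: c.n_excluded_from_lambda for c in calibration
        }
    meta["n_results"] = len(results)
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"burden": burden_path, "qq": qq_path, "meta": meta_path}


def read_results_tsv(path: str | os.PathLike) -> list[GeneBurdenResult]:
    """Round-trip reader for the burden-result TSV."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                GeneBurdenResult(
                    gene=row["gene"],
                    variant_class=VariantClass(row["class"]),
                    case_carriers=int(row["a"]),
                    case_noncarriers=int(row["b"]),
                    control_carriers=int(row["c"]),
                    control_noncarriers=int(row["d"]),
                    p_value=float(row["p"]),
                    exome_wide_significant=bool(int(row["significant"])),
                )
            )
    return out
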