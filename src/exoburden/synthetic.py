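"""Seeded generator of case/control exome cohorts for the burden pipeline.

The generator emulates the statistical structure a collapsing burden
analysis assumes — per-gene, per-class qualifying-variant carriers at
configurable rates, an optional planted causal gene, QC-metric noise,
rarity structure, toy transcript models for the NMD rule, kinship and
ancestry fixtures — so every downstream stage is testable without any
protected data. Defaults mirror the discovery design this package targets:
1,027 cases vs 2,733 controls, with a scaled-down universe of 2,000 genes.

Carriers are simulated directly at the gene x class level (one Bernoulli
per individual), then attributed to concrete variants with at most two
carriers each, matching the rarity regime in which qualifying variants are
near-private. QC-failing variants fail exactly one metric, making filter
attribution testable against the generated manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as eio
from .types import (
    AnnotatedVariant,
    CohortDesign,
    Consequence,
    DatabaseCount,
    GenotypeCall,
    KinshipPair,
    Sample,
    TranscriptModel,
    ValidationError,
    VariantClass,
)

_QC_CRITERIA = ("DP", "alt_fraction", "QD", "QUAL", "GQ")


@dataclass
class PlantedGene:
    """A causal gene planted into the simulation at fixed carrier rates."""

    gene: str
    variant_class: VariantClass
    case_carrier_rate: float
    control_carrier_rate: float

    def __post_init__(self) -> None:
        self.variant_class = VariantClass(self.variant_class)
        for r in (self.case_carrier_rate, self.control_carrier_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"carrier rate {r} outside [0,1] ({self.gene})")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults are the study conditions the pipeline targets: a discovery-scale
    case/control split, a 0.5% per-gene per-class null carrier rate shared
    between cases and controls, and modest fractions of QC-failing, common
    and NMD-escape variants.
    """

    seed: int = 0
    n_cases: int = 1027
    n_controls: int = 2733
    n_genes: int = 2000
    variants_per_gene_per_class: float = 2.0
    null_carrier_rate: float = 0.005
    planted_genes: list[PlantedGene] = field(default_factory=list)
    qc_fail_fraction: float = 0.05
    common_variant_fraction: float = 0.05
    nmd_escape_fraction: float = 0.10
    n_reference_samples: int = 100
    ancestry_outlier_count: int = 0
    related_pair_count: int = 0
    n_pca_markers: int = 500

    def __post_init__(self) -> None:
        for name in (
            "null_carrier_rate",
            "qc_fail_fraction",
            "common_variant_fraction",
            "nmd_escape_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0,1]")
        if self.n_genes < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("cohort and gene counts must be positive")
        valid = set(gene_names(self.n_genes))
        for pg in self.planted_genes:
            if pg.gene not in valid:
                raise ValidationError(
                    f"planted gene {pg.gene} not among the {self.n_genes} simulated genes"
                )


def gene_names(n_genes: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n_genes + 1)]


@dataclass
class GroundTruth:
    """Generator bookkeeping: what downstream stages should recover."""

    planted: list[PlantedGene]
    qualifying_carriers: dict[tuple[str, str], set[str]]  # (gene, class) -> samples
    qc_fail_counts: dict[str, int]
    n_common: int
    n_nmd_escape: int
    gene_universe: set[str]
    outlier_ids: list[str]
    related_expected_excluded: list[str]


@dataclass
class SyntheticCohort:
    """Everything :func:`generate_cohort` produces."""

    config: SimulationConfig
    cohort: CohortDesign
    variants: list[AnnotatedVariant]
    transcripts: dict[str, TranscriptModel]
    kinship_pairs: list[KinshipPair]
    pca_sample_ids: list[str]
    pca_matrix: np.ndarray
    pca_is_reference: np.ndarray
    truth: GroundTruth


def _toy_transcript(rng: np.random.Generator, tid: str, offset: int) -> TranscriptModel:
    n_exons = int(rng.integers(3, 9))
    exon_lens = 3 * rng.integers(40, 220, size=n_exons)
    exons = []
    pos = offset
    for L in exon_lens:
        exons.append((pos, pos + int(L) - 1))
        pos += int(L) + 200  # fixed toy intron
    return TranscriptModel(tid, "+", exons, exons[0][0], exons[-1][1])


def _nmd_boundary(tx: TranscriptModel, escape_bp: int = 50) -> int:
    lens = tx.cds_lengths_by_exon()
    return sum(lens[:-1]) - escape_bp


def _ptc_in_nmd_zone(rng: np.random.Generator, tx: TranscriptModel) -> int:
    """A PTC position that is NMD-predicted and loses >= 10% of the protein."""
    boundary = _nmd_boundary(tx)
    max_keep = int(0.89 * tx.protein_length_aa)  # keeps C-terminal loss > 10%
    hi = min(boundary - 1, 3 * max_keep)
    return int(rng.integers(1, max(hi, 2)))


def _ptc_in_escape_zone(rng: np.random.Generator, tx: TranscriptModel) -> int:
    boundary = max(_nmd_boundary(tx), 1)
    return int(rng.integers(boundary, tx.cds_length_nt + 1))


_LOF_CSQ = (Consequence.STOP_GAINED, Consequence.FRAMESHIFT, Consequence.SPLICE_CANONICAL)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic under a fixed config."""
    rng = np.random.default_rng(config.seed)
    genes = gene_names(config.n_genes)
    case_ids = [f"CASE{i:05d}" for i in range(1, config.n_cases + 1)]
    control_ids = [f"CTRL{i:05d}" for i in range(1, config.n_controls + 1)]

    samples = [
        Sample(sid, "case", "F", "cohort1", float(np.round(d, 2)))
        for sid, d in zip(case_ids, np.clip(rng.normal(114, 15, config.n_cases), 31, None))
    ] + [
        Sample(sid, "control", "F", "controls", float(np.round(d, 2)))
        for sid, d in zip(
            control_ids, np.clip(rng.normal(108, 15, config.n_controls), 31, None)
        )
    ]
    cohort = CohortDesign(samples)

    transcripts = {}
    gene_tx = {}
    offset = 1000
    for i, gene in enumerate(genes, start=1):
        tid = f"TX{i:04d}"
        tx = _toy_transcript(rng, tid, offset)
        offset = max(e for _, e in tx.exons) + 10_000
        transcripts[tid] = tx
        gene_tx[gene] = tid

    planted_by_key = {
        (pg.gene, pg.variant_class): pg for pg in config.planted_genes
    }

    variants: list[AnnotatedVariant] = []
    truth_carriers: dict[tuple[str, str], set[str]] = {}
    qc_fail_counts = {c: 0 for c in _QC_CRITERIA}
    n_common = 0
    n_escape = 0
    universe: set[str] = set()
    var_serial = 0

    def passing_metrics():
        return dict(
            mean_DP=float(rng.uniform(15, 60)),
            mean_QD=float(rng.uniform(12, 35)),
            mean_QUAL=float(rng.uniform(40, 120)),
        )

    def carrier_genotype(sid: str, gq_low: float = 30.0, alt_low: float = 0.30):
        dp = int(rng.integers(15, 61))
        return GenotypeCall(
            sid,
            1,
            dp,
            float(rng.uniform(alt_low, 0.60)),
            float(rng.integers(int(gq_low), 100)),
        )

    all_ids = case_ids + control_ids

    def internal_afs(genotypes: Sequence[GenotypeCall]) -> dict[str, float]:
        ac_case = sum(g.allele_count for g in genotypes if g.sample_id.startswith("CASE"))
        ac_ctrl = sum(g.allele_count for g in genotypes if g.sample_id.startswith("CTRL"))
        return {
            "cases": ac_case / (2 * config.n_cases),
            "controls": ac_ctrl / (2 * config.n_controls),
        }

    case_arr = np.array(case_ids)
    control_arr = np.array(control_ids)

    # Max carriers per variant such that the in-cohort allele frequency of a
    # (heterozygous) qualifying variant stays below the 0.1% rarity bound in
    # both cohorts; the near-private regime uses at most 2. Cohorts smaller
    # than ~500 per arm cannot satisfy the bound with any carrier at all —
    # the generator then emits private variants and the caller must relax
    # the rarity threshold to study them.
    cap = min(
        math.ceil(0.002 * config.n_cases) - 1,
        math.ceil(0.002 * config.n_controls) - 1,
    )
    per_variant = max(1, min(2, cap))

    for gene in genes:
        tid = gene_tx[gene]
        tx = transcripts[tid]
        chrom = "1"
        base_pos = min(s for s, _ in tx.exons)
        for cls in (VariantClass.LOF, VariantClass.DAMAGING_MISSENSE, VariantClass.SYNONYMOUS):
            planted = planted_by_key.get((gene, cls))
            case_rate = planted.case_carrier_rate if planted else config.null_carrier_rate
            control_rate = (
                planted.control_carrier_rate if planted else config.null_carrier_rate
            )
            carriers = list(case_arr[rng.random(config.n_cases) < case_rate]) + list(
                control_arr[rng.random(config.n_controls) < control_rate]
            )
            # shuffle before attributing to variants so that any later
            # variant-level removal (e.g. NMD escape) thins carriers without
            # regard to case/control status
            carriers = [carriers[i] for i in rng.permutation(len(carriers))]

            # Extra non-qualifying variants (QC failures / common variants);
            # carriers of the tested class come only from the Bernoulli draw
            # above, so realized carrier rates match the configured rates.
            n_extra = int(rng.poisson(config.variants_per_gene_per_class))
            n_carrier_vars = math.ceil(len(carriers) / per_variant)
            roles: list[str] = []
            for _ in range(n_extra):
                u = rng.random()
                if u < config.qc_fail_fraction:
                    roles.append("fail")
                elif u < config.qc_fail_fraction + config.common_variant_fraction:
                    roles.append("common")

            qualifying: set[str] = set()
            n_surviving_qvs = 0
            # carrier-bearing passing variants, <= 2 carriers each (near-private)
            for vi in range(n_carrier_vars):
                var_serial += 1
                sub = carriers[per_variant * vi : per_variant * (vi + 1)]
                genotypes = [carrier_genotype(s) for s in sub]
                csq, ptc, flags, escaped = _consequence_for(
                    rng, cls, tx, config, planted is not None
                )
                v = AnnotatedVariant(
                    variant_id=f"{chrom}:{base_pos + var_serial}:A:T",
                    gene=gene,
                    transcript_id=tid,
                    consequence=csq,
                    predictor_flags=flags,
                    internal_af_by_cohort=internal_afs(genotypes),
                    external_af_by_db={},
                    genotypes=genotypes,
                    cds_ptc_position=ptc,
                    **passing_metrics(),
                )
                variants.append(v)
                if escaped:
                    n_escape += 1
                else:
                    qualifying.update(sub)
                    n_surviving_qvs += 1
            # extra variants: decoys, QC failures, common variants
            for role in roles:
                var_serial += 1
                sid = all_ids[int(rng.integers(0, len(all_ids)))]
                metrics = passing_metrics()
                genotypes = [carrier_genotype(sid)]
                external: dict[str, float] = {}
                csq, ptc, flags, escaped = _consequence_for(
                    rng, cls, tx, config, planted=False
                )
                if role == "fail":
                    crit = _QC_CRITERIA[int(rng.integers(0, len(_QC_CRITERIA)))]
                    qc_fail_counts[crit] += 1
                    if crit == "DP":
                        metrics["mean_DP"] = float(rng.uniform(2, 10))
                    elif crit == "QD":
                        metrics["mean_QD"] = float(rng.uniform(1, 10))
                    elif crit == "QUAL":
                        metrics["mean_QUAL"] = float(rng.uniform(5, 30))
                    elif crit == "alt_fraction":
                        genotypes = [
                            GenotypeCall(
                                sid,
                                1,
                                int(rng.integers(15, 61)),
                                float(rng.uniform(0.05, 0.24)),
                                float(rng.integers(30, 100)),
                            )
                        ]
                    elif crit == "GQ":
                        genotypes = [
                            GenotypeCall(
                                sid,
                                1,
                                int(rng.integers(15, 61)),
                                float(rng.uniform(0.30, 0.60)),
                                float(rng.integers(1, 21)),
                            )
                        ]
                elif role == "common":
                    n_common += 1
                    external["popdb"] = float(rng.uniform(0.001, 0.05))
                v = AnnotatedVariant(
                    variant_id=f"{chrom}:{base_pos + var_serial}:A:T",
                    gene=gene,
                    transcript_id=tid,
                    consequence=csq,
                    predictor_flags=flags,
                    internal_af_by_cohort=internal_afs(genotypes),
                    external_af_by_db=external,
                    genotypes=genotypes,
                    cds_ptc_position=ptc,
                    **metrics,
                )
                variants.append(v)
            if qualifying:
                truth_carriers[(gene, cls.value)] = qualifying
            if qualifying or n_surviving_qvs:
                universe.add(gene)

    # kinship fixture: related pairs among cases plus an equal number of
    # sub-threshold pairs
    kinship_pairs: list[KinshipPair] = []
    related_expected: list[str] = []
    if config.related_pair_count:
        chosen = rng.choice(
            len(case_ids), size=2 * config.related_pair_count, replace=False
        )
        for j in range(config.related_pair_count):
            a = case_ids[int(chosen[2 * j])]
            b = case_ids[int(chosen[2 * j + 1])]
            kinship_pairs.append(KinshipPair(a, b, float(rng.uniform(0.177, 0.354))))
            sa, sb = cohort.sample(a), cohort.sample(b)
            if sa.mean_coding_depth < sb.mean_coding_depth:  # type: ignore[operator]
                related_expected.append(a)
            elif sb.mean_coding_depth < sa.mean_coding_depth:  # type: ignore[operator]
                related_expected.append(b)
            else:
                related_expected.append(max(a, b))
        spare = rng.choice(len(control_ids), size=2 * config.related_pair_count, replace=False)
        for j in range(config.related_pair_count):
            kinship_pairs.append(
                KinshipPair(
                    control_ids[int(spare[2 * j])],
                    control_ids[int(spare[2 * j + 1])],
                    float(rng.uniform(0.02, 0.08)),
                )
            )

    # PCA fixture: one study population, a divergent reference panel, and
    # injected outliers drawn from mirrored allele frequencies
    p_study = rng.uniform(0.05, 0.95, config.n_pca_markers)
    p_ref = np.clip(p_study + rng.normal(0, 0.1, config.n_pca_markers), 0.01, 0.99)
    ref_ids = [f"REF{i:04d}" for i in range(1, config.n_reference_samples + 1)]
    pca_ids = all_ids + ref_ids
    n_study = len(all_ids)
    matrix = np.empty((len(pca_ids), config.n_pca_markers), dtype=np.int8)
    matrix[:n_study] = rng.binomial(2, p_study, size=(n_study, config.n_pca_markers))
    matrix[n_study:] = rng.binomial(
        2, p_ref, size=(len(ref_ids), config.n_pca_markers)
    )
    outlier_ids: list[str] = []
    for j in range(config.ancestry_outlier_count):
        idx = j * 2  # alternate cases (even) / controls via offset
        if idx >= n_study:
            break
        outlier_ids.append(pca_ids[idx])
        matrix[idx] = rng.binomial(2, 1.0 - p_study, size=config.n_pca_markers)
    is_reference = np.array([i >= n_study for i in range(len(pca_ids))])

    truth = GroundTruth(
        planted=list(config.planted_genes),
        qualifying_carriers=truth_carriers,
        qc_fail_counts=qc_fail_counts,
        n_common=n_common,
        n_nmd_escape=n_escape,
        gene_universe=universe,
        outlier_ids=outlier_ids,
        related_expected_excluded=related_expected,
    )
    return SyntheticCohort(
        config=config,
        cohort=cohort,
        variants=variants,
        transcripts=transcripts,
        kinship_pairs=kinship_pairs,
        pca_sample_ids=pca_ids,
        pca_matrix=matrix,
        pca_is_reference=is_reference,
        truth=truth,
    )


def _consequence_for(
    rng: np.random.Generator,
    cls: VariantClass,
    tx: TranscriptModel,
    config: SimulationConfig,
    planted: bool,
):
    """Draw (consequence, ptc, predictor_flags, escaped) for one variant."""
    if cls is VariantClass.LOF:
        u = rng.random()
        if u < 0.5:
            csq = Consequence.STOP_GAINED
        elif u < 0.8:
            csq = Consequence.FRAMESHIFT
        else:
            csq = Consequence.SPLICE_CANONICAL
        if csq is Consequence.SPLICE_CANONICAL:
            return csq, None, None, False
        escaped = (not planted) and rng.random() < config.nmd_escape_fraction
        ptc = (
            _ptc_in_escape_zone(rng, tx) if escaped else _ptc_in_nmd_zone(rng, tx)
        )
        return csq, ptc, None, escaped
    if cls is VariantClass.DAMAGING_MISSENSE:
        return Consequence.MISSENSE, None, (True, True, True), False
    return Consequence.SYNONYMOUS, None, None, False


def generate_toy_transcript(
    n_exons: int,
    exon_lengths: Sequence[int],
    ptc_offset: int,
    transcript_id: str = "TXTOY",
    gene: str = "GENETOY",
) -> tuple[TranscriptModel, AnnotatedVariant]:
    """Build a fully-coding plus-strand toy transcript and a PTC variant.

    The returned nonsense variant's ``cds_ptc_position`` sits exactly
    ``ptc_offset`` nucleotides upstream of the CDS 3' end, enabling boundary
    tests of the 50-bp penultimate-exon rule.
    """
    if n_exons < 2:
        raise ValidationError("need at least 2 exons")
    if len(exon_lengths) != n_exons:
        raise ValidationError("exon_lengths must have n_exons entries")
    cds_length = sum(exon_lengths)
    if cds_length % 3 != 0:
        raise ValidationError("total exon length must be divisible by 3")
    if not 0 <= ptc_offset < cds_length:
        raise ValidationError("ptc_offset must be in [0, cds_length)")
    exons = []
    pos = 1000
    for L in exon_lengths:
        exons.append((pos, pos + L - 1))
        pos += L + 100
    tx = TranscriptModel(transcript_id, "+", exons, exons[0][0], exons[-1][1])
    ptc = cds_length - ptc_offset
    variant = AnnotatedVariant(
        variant_id=f"1:{exons[0][0]}:C:G",
        gene=gene,
        transcript_id=transcript_id,
        consequence=Consequence.STOP_GAINED,
        predictor_flags=None,
        mean_QD=20.0,
        mean_QUAL=60.0,
        mean_DP=40.0,
        internal_af_by_cohort={"cases": 0.0001, "controls": 0.0},
        genotypes=[GenotypeCall("CASE00001", 1, 40, 0.5, 60.0)],
        cds_ptc_position=ptc,
    )
    return tx, variant


def synthetic_database_counts() -> list[DatabaseCount]:
    """Synthetic population-database carrier-count table.

    A stand-in for the per-database carrier tallies of six public genomic
    resources: carrier counts and order-of-magnitude denominators are chosen
    so that each source's carrier frequency matches the published per-source
    frequency (0%, 0%, 0.0094%, 0.0014%, 0.0093% and 0.014%) at its printed
    rounding, with a 63/50 female/male split among the carriers of the
    largest source. The table is synthetic; it is not a copy of any
    database's release data.
    """
    return [
        DatabaseCount("huabiao_syn", 0, 2739),
        DatabaseCount("nyuwa_syn", 0, 2902),
        DatabaseCount("chinamap_syn", 1, 10588),
        DatabaseCount("mcps_syn", 2, 141046),
        DatabaseCount("bravo_syn", 12, 129032),
        DatabaseCount("gnomad_syn", 113, 807162, carriers_by_sex=(63, 50)),
    ]


def write_fixture(
    sim: SyntheticCohort,
    out_dir: str | Path,
    dialect: str = "tsv",
) -> Path:
    """Write a complete, immediately runnable input set plus the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dialect == "tsv":
        eio.write_variant_tsv(sim.variants, out / "variants.tsv")
    elif dialect == "vcf":
        eio.write_variant_vcf(
            sim.variants,
            out / "variants.vcf",
            [s.sample_id for s in sim.cohort.samples],
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    gene_of = {f"TX{i:04d}": g for i, g in enumerate(gene_names(sim.config.n_genes), 1)}
    eio.write_transcript_gtf(sim.transcripts.values(), out / "transcripts.gtf", gene_of=gene_of)
    eio.write_cohort_tsv(sim.cohort, out / "cohort.tsv")
    eio.write_kinship_tsv(sim.kinship_pairs, out / "kinship.tsv")
    eio.write_genotype_matrix_tsv(
        sim.pca_sample_ids, sim.pca_matrix, out / "genotype_matrix.tsv"
    )
    eio.write_database_counts_tsv(synthetic_database_counts(), out / "database_counts.tsv")
    manifest = {
        "seed": sim.config.seed,
        "n_cases": sim.config.n_cases,
        "n_controls": sim.config.n_controls,
        "n_genes": sim.config.n_genes,
        "planted": [
            {
                "gene": pg.gene,
                "class": pg.variant_class.value,
                "case_carrier_rate": pg.case_carrier_rate,
                "control_carrier_rate": pg.control_carrier_rate,
                "realized_case_carriers": sum(
                    1
                    for s in sim.truth.qualifying_carriers.get(
                        (pg.gene, pg.variant_class.value), set()
                    )
                    if s.startswith("CASE")
                ),
                "realized_control_carriers": sum(
                    1
                    for s in sim.truth.qualifying_carriers.get(
                        (pg.gene, pg.variant_class.value), set()
                    )
                    if s.startswith("CTRL")
                ),
            }
            for pg in sim.truth.planted
        ],
        "qc_fail_counts": sim.truth.qc_fail_counts,
        "n_common": sim.truth.n_common,
        "n_nmd_escape": sim.truth.n_nmd_escape,
        "gene_universe_size": len(sim.truth.gene_universe),
        "outlier_ids": sim.truth.outlier_ids,
        "related_expected_excluded": sim.truth.related_expected_excluded,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
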