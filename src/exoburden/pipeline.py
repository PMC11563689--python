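"""End-to-end pipeline driver: configuration, staging, logging, artifacts.

The pipeline executes sample QC -> variant classification -> qualifying-
variant selection -> burden testing -> permutation calibration ->
prevalence, writing machine-readable TSV/JSON artifacts plus a plain-text
log with per-stage counts. A single global seed fans out to per-stage seeds
by fixed offsets so stages are independently reproducible; identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import io as eio
from .burden import BurdenConfig, run_exome_burden
from .calibration import PermutationConfig, calibrate
from .lof import DEFAULT_NMD_PARAMS, NmdRuleParams, classify_variants, write_classification_tsv
from .prevalence import carrier_frequency, enrichment_ratio, pooled_prevalence, sex_ratio_test
from .sample_qc import KINSHIP_2ND_DEGREE, filter_by_depth, pca_ancestry_filter, prune_related
from .variant_qc import (
    DEFAULT_THRESHOLDS,
    QvThresholds,
    select_qualifying_variants,
    write_attrition_tsv,
    write_qv_sets_tsv,
)
from .types import ValidationError, VariantClass

logger = logging.getLogger("exoburden")

#: Fixed offset between the global seed and the permutation-stage seed.
PERMUTATION_SEED_OFFSET = 101


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    variants_path: str
    transcripts_path: str
    cohort_path: str
    out_dir: str
    variants_dialect: str = "tsv"
    transcripts_dialect: str = "gtf"
    kinship_path: Optional[str] = None
    genotype_matrix_path: Optional[str] = None
    database_counts_path: Optional[str] = None
    seed: int = 0
    min_depth: float = 30.0
    kinship_threshold: float = KINSHIP_2ND_DEGREE
    pca_sd_multiplier: float = 4.0
    thresholds: QvThresholds = field(default_factory=QvThresholds)
    nmd_params: NmdRuleParams = field(default_factory=NmdRuleParams)
    burden: BurdenConfig = field(default_factory=BurdenConfig)
    n_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (
            ("thresholds", QvThresholds),
            ("nmd_params", NmdRuleParams),
            ("burden", BurdenConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        base = Path(path).parent
        cfg = cls(**raw)
        # resolve relative input paths against the config file's directory
        for attr in (
            "variants_path",
            "transcripts_path",
            "cohort_path",
            "kinship_path",
            "genotype_matrix_path",
            "database_counts_path",
            "out_dir",
        ):
            val = getattr(cfg, attr)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        return cfg

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        for attr in ("variants_path", "transcripts_path", "cohort_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise ValidationError(f"{attr} does not exist: {p}")
        for attr in ("kinship_path", "genotype_matrix_path", "database_counts_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{attr} does not exist: {p}")


STAGES = ("load", "sample_qc", "classify", "variant_qc", "burden", "calibrate", "prevalence")


def run_pipeline(config: RunConfig, stop_after: Optional[str] = None) -> Path:
    """Run the pipeline, writing all artifacts into ``config.out_dir``.

    ``stop_after`` names a stage from :data:`STAGES` to halt after (used by
    the per-stage CLI subcommands). Any stage error aborts with the stage
    name and cause.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def run_stage(name, fn):
        if _stage_index(name) > _stage_index(stop_after):
            return None
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc

    def _stage_index(name):
        return STAGES.index(name) if name else len(STAGES)

    state: dict = {}

    def _load():
        state["variants"] = eio.read_variant_table(
            config.variants_path, config.variants_dialect
        )
        state["transcripts"] = eio.read_transcript_models(
            config.transcripts_path, config.transcripts_dialect
        )
        state["cohort"] = eio.read_cohort_tsv(config.cohort_path)
        state["kinship"] = (
            eio.read_kinship_tsv(config.kinship_path) if config.kinship_path else []
        )
        if config.genotype_matrix_path:
            state["pca_ids"], state["pca_matrix"] = eio.read_genotype_matrix_tsv(
                config.genotype_matrix_path
            )
        state["db_counts"] = (
            eio.read_database_counts_tsv(config.database_counts_path)
            if config.database_counts_path
            else []
        )
        log(
            f"load: {len(state['variants'])} variants, "
            f"{len(state['transcripts'])} transcripts, "
            f"{len(state['cohort'].samples)} samples"
        )

    def _sample_qc():
        cohort = state["cohort"]
        _, excl_depth = filter_by_depth(cohort, config.min_depth)
        _, excl_rel = prune_related(cohort, state["kinship"], config.kinship_threshold)
        excl_pca: list[str] = []
        if "pca_matrix" in state:
            ids = state["pca_ids"]
            is_ref = [sid not in cohort for sid in ids]
            _, excl_pca, projections = pca_ancestry_filter(
                state["pca_matrix"], ids, is_ref, config.pca_sd_multiplier
            )
            for sid in excl_pca:
                cohort.exclude(sid, "ancestry_outlier")
            with open(out / "pca_scores.tsv", "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["sample_id", "pc1", "pc2", "retained"])
                for pr in projections:
                    w.writerow(
                        [
                            pr.sample_id,
                            "%.12g" % pr.pc_scores[0],
                            "%.12g" % pr.pc_scores[1],
                            int(pr.retained),
                        ]
                    )
        log(
            f"sample_qc: excluded {len(excl_depth)} low-depth, "
            f"{len(excl_rel)} related, {len(excl_pca)} ancestry outliers; "
            f"{cohort.n_cases} cases / {cohort.n_controls} controls remain"
        )

    def _classify():
        state["classifications"] = classify_variants(
            state["variants"], state["transcripts"], config.nmd_params
        )
        write_classification_tsv(
            state["classifications"].values(), out / "classification.tsv"
        )
        n_lof = sum(
            1
            for r in state["classifications"].values()
            if r.variant_class is VariantClass.LOF
        )
        log(f"classify: {len(state['classifications'])} variants, {n_lof} LoF")

    def _variant_qc():
        sel = select_qualifying_variants(
            state["variants"], state["classifications"], config.thresholds
        )
        state["selection"] = sel
        write_attrition_tsv(sel, out / "attrition.tsv")
        write_qv_sets_tsv(sel, out / "qv_sets.tsv")
        log(
            f"variant_qc: {sel.n_qualifying}/{sel.n_input} qualifying, "
            f"universe {sel.universe_size} genes; attrition "
            + ", ".join(f"{k}={v}" for k, v in sorted(sel.attrition.items()))
        )

    def _burden():
        results, G, threshold = run_exome_burden(
            state["selection"].qv_sets, state["cohort"], config.burden
        )
        state["results"], state["G"], state["threshold"] = results, G, threshold
        sig = [r for r in results if r.exome_wide_significant]
        log(
            f"burden: G={G}, threshold={threshold:.3g}, "
            f"{len(sig)} exome-wide significant"
        )

    def _calibrate():
        perm = PermutationConfig(
            n_permutations=config.n_permutations,
            seed=config.seed + PERMUTATION_SEED_OFFSET,
        )
        state["calibration"] = calibrate(
            state["selection"].qv_sets,
            state["cohort"],
            state["results"],
            state["threshold"],
            perm,
            config.burden,
        )
        lams = {
            c.variant_class.value: round(c.lambda_inflation, 4)
            for c in state["calibration"]
        }
        log(f"calibrate: lambda per class {lams}")

    def _prevalence():
        rows = []
        counts = state["db_counts"]
        if counts:
            for c in counts:
                est = carrier_frequency(c.carriers, c.denominator, source_label=c.source_label)
                rows.append(est)
            pooled = pooled_prevalence(counts)
            rows.append(pooled)
            # case carrier frequency of the top LoF hit, if any
            lof = [
                r
                for r in state.get("results", [])
                if r.variant_class is VariantClass.LOF
            ]
            if lof:
                top = lof[0]
                case_est = carrier_frequency(
                    top.case_carriers,
                    top.case_carriers + top.case_noncarriers,
                    source_label=f"cases_{top.gene}",
                )
                rows.append(case_est)
                if pooled.frequency > 0:
                    ratio, p_enrich = enrichment_ratio(case_est, pooled)
                    log(
                        f"prevalence: top-gene case frequency {case_est.frequency:.4%}, "
                        f"pooled population {pooled.frequency:.4%}, "
                        f"ratio {ratio:.0f} (P={p_enrich:.3g})"
                    )
            for c in counts:
                if c.carriers_by_sex:
                    kf, km = c.carriers_by_sex
                    p_sex = sex_ratio_test(kf, km)
                    log(
                        f"prevalence: {c.source_label} carrier sex split "
                        f"{kf}F/{km}M, binomial P={p_sex:.3g}"
                    )
            with open(out / "prevalence.tsv", "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["source", "carriers", "n", "frequency", "ci_low", "ci_high"])
                for est in rows:
                    w.writerow(
                        [
                            est.source_label,
                            est.carriers,
                            est.denominator,
                            "%.12g" % est.frequency,
                            "%.12g" % est.ci_low,
                            "%.12g" % est.ci_high,
                        ]
                    )
        state["prevalence"] = rows

    run_stage("load", _load)
    run_stage("sample_qc", _sample_qc)
    run_stage("classify", _classify)
    run_stage("variant_qc", _variant_qc)
    run_stage("burden", _burden)
    run_stage("calibrate", _calibrate)
    run_stage("prevalence", _prevalence)

    if "results" in state:
        meta = {
            "seed": config.seed,
            "thresholds": asdict(config.thresholds),
            "nmd_params": asdict(config.nmd_params),
            "alpha": config.burden.alpha,
            "n_permutations": config.n_permutations,
            "min_depth": config.min_depth,
            "kinship_threshold": config.kinship_threshold,
            "pca_sd_multiplier": config.pca_sd_multiplier,
            "G": state["G"],
            "bonferroni_threshold": state["threshold"],
            "n_cases": state["cohort"].n_cases,
            "n_controls": state["cohort"].n_controls,
            "samples_excluded": dict(
                sorted(
                    (sid, reason)
                    for sid, reason in state["cohort"].qc_excluded.items()
                )
            ),
            "significant_genes": [
                [r.gene, r.variant_class.value]
                for r in state["results"]
                if r.exome_wide_significant
            ],
        }
        eio.write_results(
            state["results"], state.get("calibration"), out / "results", metadata=meta
        )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
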