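"""Permutation-based expected P distributions, QQ coordinates and lambda.

The expected null distribution of burden P values comes from relabeling
case/control status (preserving group sizes) and re-running the full burden
scan; the expected P at rank i is the across-permutation mean of the i-th
smallest P. The genomic inflation factor lambda is the slope of observed vs
expected -log10 P through the origin, after excluding observed P values of
1.0 and those beyond the Bonferroni threshold (so true signal does not
inflate lambda).

Because genotypes, QC and classification are label-independent, a
permutation scan only needs the per-gene carrier sets; re-testing reduces to
counting how many carriers land in the shuffled case group and looking the
table up in a cached per-margin Fisher P table. This is exact — identical to
re-running the scan per permutation — and is what makes 1,000 permutations
over ~20,000 genes tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from scipy import stats

from .burden import BurdenConfig, fisher_midp_table, fisher_table_pvalues, run_exome_burden
from .types import (
    AnnotatedVariant,
    CalibrationResult,
    CohortDesign,
    GeneBurdenResult,
    ValidationError,
    VariantClass,
)


@dataclass(frozen=True)
class PermutationConfig:
    """Number of case/control relabelings and the RNG seed."""

    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


class _ClassCarrierIndex:
    """Flat carrier-index representation of one class's qualifying variants."""

    def __init__(self, gene_order: list[str], carrier_sets: list[set[int]]):
        self.genes = gene_order
        self.m = np.array([len(s) for s in carrier_sets], dtype=np.int64)
        self.flat = np.concatenate(
            [np.fromiter(sorted(s), dtype=np.int64, count=len(s)) for s in carrier_sets]
        ) if carrier_sets and self.m.sum() else np.empty(0, dtype=np.int64)
        self.gene_of_entry = np.repeat(np.arange(len(gene_order)), self.m)

    def case_counts(self, case_mask: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.gene_of_entry,
            weights=case_mask[self.flat],
            minlength=len(self.genes),
        ).astype(np.int64)


def _build_indices(
    qv_sets: Mapping[tuple[str, VariantClass], Sequence[AnnotatedVariant]],
    cohort: CohortDesign,
    classes: Sequence[VariantClass],
) -> tuple[dict[VariantClass, _ClassCarrierIndex], np.ndarray]:
    passing = cohort.passing()
    idx_of = {s.sample_id: i for i, s in enumerate(passing)}
    case_mask = np.array([s.status == "case" for s in passing], dtype=float)
    indices = {}
    for cls in classes:
        genes = sorted({g for (g, c) in qv_sets if c == cls})
        carrier_sets = []
        for gene in genes:
            carriers: set[int] = set()
            for v in qv_sets[(gene, cls)]:
                for sid in v.carriers:
                    i = idx_of.get(sid)
                    if i is not None:
                        carriers.add(i)
            carrier_sets.append(carriers)
        indices[cls] = _ClassCarrierIndex(genes, carrier_sets)
    return indices, case_mask


def permutation_expected(
    qv_sets: Mapping[tuple[str, VariantClass], Sequence[AnnotatedVariant]],
    cohort: CohortDesign,
    perm_config: PermutationConfig,
    burden_config: BurdenConfig = BurdenConfig(),
) -> dict[VariantClass, np.ndarray]:
    """Across-permutation mean of rank-ordered P values, per variant class.

    Each output array is sorted ascending and has one entry per gene tested
    in that class, aligned with the rank-ordered observed P values.
    """
    indices, case_mask = _build_indices(qv_sets, cohort, burden_config.classes)
    n_cases = int(case_mask.sum())
    n_controls = case_mask.size - n_cases
    rng = np.random.default_rng(perm_config.seed)

    # Per-class lookup tables: p_table[g, a] = Fisher P at a case carriers.
    tables = {}
    for cls, index in indices.items():
        if not index.genes:
            continue
        max_m = int(index.m.max()) if index.m.size else 0
        per_m = {}
        lut = np.empty((len(index.genes), max_m + 1))
        lut.fill(np.nan)
        for g, m in enumerate(index.m):
            m = int(m)
            if m not in per_m:
                per_m[m] = fisher_table_pvalues(n_cases, n_controls, m)
            lut[g, : m + 1] = per_m[m][: m + 1]
        tables[cls] = lut

    sums = {cls: np.zeros(len(indices[cls].genes)) for cls in tables}
    for _ in range(perm_config.n_permutations):
        perm_mask = rng.permutation(case_mask)
        for cls, lut in tables.items():
            index = indices[cls]
            a = index.case_counts(perm_mask)
            p = lut[np.arange(len(index.genes)), a]
            p.sort()
            sums[cls] += p
    return {cls: sums[cls] / perm_config.n_permutations for cls in sums}


def discreteness_adjusted_p(
    qv_sets: Mapping[tuple[str, VariantClass], Sequence[AnnotatedVariant]],
    cohort: CohortDesign,
    burden_config: BurdenConfig = BurdenConfig(),
    rng: Optional[np.random.Generator] = None,
) -> dict[VariantClass, np.ndarray]:
    """Per-class discreteness-adjusted P values of the observed burden scan.

    An exact test's P value is stochastically larger than uniform under the
    null because its support is discrete. The adjustment replaces each P by
    ``P - V * Pr(P = p_obs)``: with ``V = 1/2`` (the default, ``rng=None``)
    this is the mid-P / midrank adjustment, which restores uniformity in
    mean; with ``V ~ Uniform(0,1)`` (pass a generator) it is the randomized
    probability-integral transform, which is *exactly* Uniform(0,1) under
    the null and therefore suitable for a distribution-level KS check. The
    mid-P variant retains atoms at the support midpoints — with thousands
    of genes sharing the same cohort margins those atoms align and a KS
    test will reject even a perfectly calibrated scan, so use the
    randomized variant for testing uniformity.
    """
    indices, case_mask = _build_indices(qv_sets, cohort, burden_config.classes)
    n_cases = int(case_mask.sum())
    n_controls = case_mask.size - n_cases
    out = {}
    for cls, index in indices.items():
        if not index.genes:
            continue
        per_p: dict[int, np.ndarray] = {}
        per_pmf: dict[int, np.ndarray] = {}
        a = index.case_counts(case_mask)
        p_obs = np.empty(len(index.genes))
        pmf_obs = np.empty(len(index.genes))
        for g, m in enumerate(index.m):
            m = int(m)
            if m not in per_p:
                p = fisher_table_pvalues(n_cases, n_controls, m)
                midp = fisher_midp_table(n_cases, n_controls, m)
                per_p[m] = p
                per_pmf[m] = 2.0 * (p - midp)  # point probability
            p_obs[g] = per_p[m][int(a[g])]
            pmf_obs[g] = per_pmf[m][int(a[g])]
        v = 0.5 if rng is None else rng.random(len(index.genes))
        out[cls] = np.clip(p_obs - v * pmf_obs, 1e-300, 1.0)
    return out


def uniformity_check(
    adjusted_p: Sequence[float], alpha: float = 0.01
) -> tuple[bool, float]:
    """Kolmogorov-Smirnov test of adjusted P values against Uniform(0,1).

    Feed it the randomized-PIT output of :func:`discreteness_adjusted_p`.
    Returns ``(consistent_with_uniform, ks_p_value)``.
    """
    ks = stats.kstest(np.asarray(adjusted_p, dtype=float), "uniform")
    return bool(ks.pvalue > alpha), float(ks.pvalue)


def lambda_inflation(
    observed_p: Sequence[float],
    expected_p: Sequence[float],
    bonferroni_threshold: float,
    free_intercept: bool = False,
) -> tuple[float, int]:
    """Inflation factor: regression slope of observed on expected -log10 P.

    Rank pairs with observed P equal to 1.0, or observed P beyond the
    Bonferroni threshold (more significant), are excluded so that neither
    the uninformative mass at P = 1 nor true signal distorts the slope. The
    default regression is least squares through the origin on the -log10
    scale; ``free_intercept`` switches to ordinary least squares and
    reports its slope.
    """
    obs = np.asarray(observed_p, dtype=float)
    exp = np.asarray(expected_p, dtype=float)
    if obs.shape != exp.shape:
        raise ValidationError("observed/expected lists must have equal length")
    keep = (obs < 1.0) & (obs >= bonferroni_threshold)
    n_excluded = int((~keep).sum())
    x = -np.log10(exp[keep])
    y = -np.log10(obs[keep])
    if x.size < 2:
        raise ValidationError("fewer than 2 rank pairs survive lambda exclusions")
    if free_intercept:
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
    return slope, n_excluded


def calibrate(
    qv_sets: Mapping[tuple[str, VariantClass], Sequence[AnnotatedVariant]],
    cohort: CohortDesign,
    results: Sequence[GeneBurdenResult],
    bonferroni_threshold: float,
    perm_config: PermutationConfig,
    burden_config: BurdenConfig = BurdenConfig(),
) -> list[CalibrationResult]:
    """Full calibration: expected P per rank and lambda for each class."""
    expected = permutation_expected(qv_sets, cohort, perm_config, burden_config)
    out = []
    for cls in burden_config.classes:
        obs = sorted(r.p_value for r in results if r.variant_class == cls)
        if not obs:
            continue
        exp = expected[cls]
        if len(exp) != len(obs):
            raise ValidationError(
                f"expected/observed length mismatch for class {cls.value}"
            )
        lam, n_excl = lambda_inflation(obs, exp, bonferroni_threshold)
        out.append(
            CalibrationResult(
                variant_class=cls,
                observed_p=list(obs),
                expected_p=[float(e) for e in exp],
                lambda_inflation=lam,
                n_excluded_from_lambda=n_excl,
            )
        )
    return out
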