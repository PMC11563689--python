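"""Sample pruning: coverage, relatedness and PCA ancestry-outlier filters.

The three filters mirror standard case-control exome QC: drop samples with
mean coding depth below x30, drop the lower-coverage member of every related
pair (KING kinship at or above the 2nd-degree bound, 0.0884), and drop
ancestry outliers falling more than 4 standard deviations from the study
mean on principal component 1 or 2 of a common-marker genotype matrix.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .types import CohortDesign, KinshipPair, PcaProjection, ValidationError

#: KING kinship lower bound for 2nd-degree relatives.
KINSHIP_2ND_DEGREE = 0.0884


def filter_by_depth(
    cohort: CohortDesign, min_depth: float = 30.0
) -> tuple[list[str], list[str]]:
    """Exclude samples with mean coding depth strictly below ``min_depth``.

    Returns (kept_ids, excluded_ids); exclusions are recorded on the cohort
    with reason ``"low_depth"``. A sample at exactly the threshold is kept.
    """
    kept, excluded = [], []
    for s in cohort.samples:
        if s.mean_coding_depth is None:
            raise ValidationError(f"sample {s.sample_id} has no mean_coding_depth")
        if s.mean_coding_depth < min_depth:
            cohort.exclude(s.sample_id, "low_depth")
            excluded.append(s.sample_id)
        else:
            kept.append(s.sample_id)
    return kept, excluded


def prune_related(
    cohort: CohortDesign,
    kinship_pairs: Sequence[KinshipPair],
    kinship_threshold: float = KINSHIP_2ND_DEGREE,
) -> tuple[list[str], list[str]]:
    """Exclude the lower-coverage member of every related pair.

    For every pair with kinship >= ``kinship_threshold`` (2nd degree or
    closer under KING conventions) the member with the lower mean coding
    depth is excluded; depth ties are broken by excluding the
    lexicographically later sample id. The per-pair rule is applied to every
    flagged pair, so after one pass no pair of retained samples remains
    related; the result is independent of pair order.
    """
    excluded: list[str] = []
    for pair in sorted(
        kinship_pairs, key=lambda p: (-p.kinship_coefficient, p.sample_a, p.sample_b)
    ):
        for sid in (pair.sample_a, pair.sample_b):
            if sid not in cohort:
                raise ValidationError(f"kinship pair references unknown sample {sid}")
        if pair.kinship_coefficient < kinship_threshold:
            continue
        sa, sb = cohort.sample(pair.sample_a), cohort.sample(pair.sample_b)
        da = sa.mean_coding_depth if sa.mean_coding_depth is not None else -math.inf
        db = sb.mean_coding_depth if sb.mean_coding_depth is not None else -math.inf
        if da < db:
            drop = sa.sample_id
        elif db < da:
            drop = sb.sample_id
        else:
            drop = max(sa.sample_id, sb.sample_id)
        if drop not in cohort.qc_excluded:
            excluded.append(drop)
        cohort.exclude(drop, "related")
    kept = [s.sample_id for s in cohort.samples if s.sample_id not in cohort.qc_excluded]
    return kept, excluded


def pca_ancestry_filter(
    genotype_matrix: np.ndarray,
    sample_ids: Sequence[str],
    is_reference: Optional[Sequence[bool]] = None,
    sd_multiplier: float = 4.0,
    n_components: int = 2,
) -> tuple[list[str], list[str], list[PcaProjection]]:
    """PCA-based ancestry-outlier exclusion on a common-marker matrix.

    Markers are standardized by the sample alternate-allele frequency
    (center ``2 * p_hat``, scale ``sqrt(2 * p_hat * (1 - p_hat))``;
    zero-variance markers dropped), principal components come from the SVD
    of the standardized matrix, and the mean and SD of PC1/PC2 are computed
    over *study* (non-reference) samples only. A study sample is excluded
    iff it deviates from the study mean by more than ``sd_multiplier``
    standard deviations on PC1 or PC2. Reference-panel samples serve as
    ancestry anchors and are never excluded.

    Returns (kept_study_ids, excluded_study_ids, projections for all samples).
    """
    X = np.asarray(genotype_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValidationError("need at least 3 samples and 2 markers for PCA")
    if len(sample_ids) != X.shape[0]:
        raise ValidationError("sample_ids length does not match matrix rows")
    ref = (
        np.zeros(X.shape[0], dtype=bool)
        if is_reference is None
        else np.asarray(is_reference, dtype=bool)
    )
    p_hat = X.mean(axis=0) / 2.0
    var = 2.0 * p_hat * (1.0 - p_hat)
    keep_markers = (var > 0) & (X.var(axis=0) > 0)
    if not keep_markers.any():
        raise ValidationError("all markers have zero variance")
    Z = (X[:, keep_markers] - 2.0 * p_hat[keep_markers]) / np.sqrt(var[keep_markers])
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, S.size)
    scores = U[:, :k] * S[:k]
    if k < 2:
        raise ValidationError("fewer than 2 principal components available")

    study = ~ref
    mean = scores[study, :2].mean(axis=0)
    sd = scores[study, :2].std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    dev = np.abs(scores[:, :2] - mean) / sd
    outlier = study & (dev > sd_multiplier).any(axis=1)

    projections = [
        PcaProjection(sid, [float(x) for x in scores[i]], retained=not outlier[i])
        for i, sid in enumerate(sample_ids)
    ]
    kept = [sid for i, sid in enumerate(sample_ids) if study[i] and not outlier[i]]
    excluded = [sid for i, sid in enumerate(sample_ids) if outlier[i]]
    return kept, excluded, projections
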