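"""Sample QC: depth filter, relatedness pruning, PCA ancestry outliers."""

from __future__ import annotations

import numpy as np
import pytest

from exoburden.sample_qc import filter_by_depth, pca_ancestry_filter, prune_related
from exoburden.types import CohortDesign, KinshipPair, Sample, ValidationError


def cohort_with_depths(depths: dict[str, float]) -> CohortDesign:
    return CohortDesign(
        [Sample(sid, "case", "F", "c1", d) for sid, d in depths.items()]
    )


class TestDepthFilter:
    def test_strict_less_than_boundary(self):
        cohort = cohort_with_depths({"A": 29.9, "B": 30.0, "C": 45.0})
        kept, excluded = filter_by_depth(cohort)
        assert excluded == ["A"] and kept == ["B", "C"]
        assert cohort.qc_excluded == {"A": "low_depth"}

    def test_counts_on_ten_sample_fixture(self):
        depths = {f"S{i}": (20.0 if i < 3 else 50.0) for i in range(10)}
        kept, excluded = filter_by_depth(cohort_with_depths(depths))
        assert len(excluded) == 3 and len(kept) == 7

    def test_missing_depth_names_sample(self):
        cohort = CohortDesign([Sample("NODEPTH", "case", "F", "c1", None)])
        with pytest.raises(ValidationError, match="NODEPTH"):
            filter_by_depth(cohort)


class TestRelatednessPruning:
    def test_lower_coverage_member_dropped(self):
        cohort = cohort_with_depths({"A": 50, "B": 40})
        kept, excluded = prune_related(cohort, [KinshipPair("A", "B", 0.25)])
        assert excluded == ["B"] and kept == ["A"]

    def test_chain_drops_both_lower_members(self):
        cohort = cohort_with_depths({"A": 50, "B": 40, "C": 30})
        pairs = [KinshipPair("A", "B", 0.2), KinshipPair("B", "C", 0.2)]
        kept, excluded = prune_related(cohort, pairs)
        assert set(excluded) == {"B", "C"} and kept == ["A"]

    def test_below_threshold_pair_untouched(self):
        cohort = cohort_with_depths({"A": 50, "B": 40})
        kept, excluded = prune_related(cohort, [KinshipPair("A", "B", 0.05)])
        assert excluded == [] and set(kept) == {"A", "B"}

    def test_depth_tie_breaks_lexicographically(self):
        cohort = cohort_with_depths({"X": 40, "Y": 40})
        _, excluded = prune_related(cohort, [KinshipPair("Y", "X", 0.25)])
        assert excluded == ["Y"]

    def test_unknown_sample_rejected(self):
        cohort = cohort_with_depths({"A": 50})
        with pytest.raises(ValidationError, match="GHOST"):
            prune_related(cohort, [KinshipPair("A", "GHOST", 0.3)])

    def test_pair_order_does_not_matter(self):
        pairs = [
            KinshipPair("A", "B", 0.20),
            KinshipPair("C", "D", 0.30),
            KinshipPair("B", "E", 0.12),
        ]
        depths = {"A": 60, "B": 55, "C": 50, "D": 45, "E": 40}
        kept1, _ = prune_related(cohort_with_depths(depths), pairs)
        kept2, _ = prune_related(cohort_with_depths(depths), pairs[::-1])
        assert kept1 == kept2

    def test_commutes_with_depth_filter_when_triggers_disjoint(self):
        depths = {"A": 25.0, "B": 50.0, "C": 45.0, "D": 60.0}
        pairs = [KinshipPair("B", "C", 0.25)]
        c1 = cohort_with_depths(depths)
        filter_by_depth(c1)
        prune_related(c1, pairs)
        c2 = cohort_with_depths(depths)
        prune_related(c2, pairs)
        filter_by_depth(c2)
        assert set(c1.qc_excluded) == set(c2.qc_excluded) == {"A", "C"}


class TestPcaAncestryFilter:
    def _inlier_matrix(self, rng, n=100, m=200):
        p = rng.uniform(0.2, 0.8, m)
        return rng.binomial(2, p, size=(n, m)), p

    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        X, _ = self._inlier_matrix(rng, n=20)
        X[1] = X[0]
        ids = [f"S{i}" for i in range(20)]
        _, _, proj = pca_ancestry_filter(X, ids)
        assert proj[0].pc_scores == pytest.approx(proj[1].pc_scores)

    def test_injected_outliers_excluded_exactly(self):
        """Five samples shifted far along PC1 (mirrored allele frequencies)
        are the only exclusions when outliers are a small minority, so they
        barely perturb the study mean and SD."""
        rng = np.random.default_rng(1)
        X, p = self._inlier_matrix(rng, n=500)
        outliers = rng.binomial(2, 1 - p, size=(5, X.shape[1]))
        full = np.vstack([X, outliers])
        ids = [f"IN{i}" for i in range(500)] + [f"OUT{i}" for i in range(5)]
        kept, excluded, _ = pca_ancestry_filter(full, ids)
        assert set(excluded) == {f"OUT{i}" for i in range(5)}
        assert len(kept) == 500

    def test_infinite_multiplier_keeps_everyone(self):
        rng = np.random.default_rng(2)
        X, _ = self._inlier_matrix(rng, n=30)
        ids = [f"S{i}" for i in range(30)]
        kept, excluded, _ = pca_ancestry_filter(X, ids, sd_multiplier=np.inf)
        assert excluded == [] and len(kept) == 30

    def test_reference_samples_never_excluded(self):
        rng = np.random.default_rng(3)
        X, p = self._inlier_matrix(rng, n=50)
        ref = rng.binomial(2, 1 - p, size=(10, X.shape[1]))  # very divergent panel
        full = np.vstack([X, ref])
        ids = [f"S{i}" for i in range(50)] + [f"R{i}" for i in range(10)]
        is_ref = [False] * 50 + [True] * 10
        kept, excluded, _ = pca_ancestry_filter(full, ids, is_ref)
        assert not any(sid.startswith("R") for sid in excluded)

    def test_marker_permutation_leaves_exclusions_invariant(self):
        rng = np.random.default_rng(4)
        X, p = self._inlier_matrix(rng, n=60)
        out = rng.binomial(2, 1 - p, size=(3, X.shape[1]))
        full = np.vstack([X, out])
        ids = [f"S{i}" for i in range(63)]
        _, excl1, _ = pca_ancestry_filter(full, ids)
        perm = rng.permutation(full.shape[1])
        _, excl2, _ = pca_ancestry_filter(full[:, perm], ids)
        assert set(excl1) == set(excl2)

    def test_degenerate_inputs_rejected(self):
        ids = ["A", "B"]
        with pytest.raises(ValidationError):
            pca_ancestry_filter(np.zeros((2, 10)), ids)
        with pytest.raises(ValidationError, match="zero variance"):
            pca_ancestry_filter(np.ones((5, 10)), [f"S{i}" for i in range(5)])
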