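"""Fisher exact test vs independent oracles; carrier collapsing; thresholds."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from exoburden.burden import (
    BurdenConfig,
    collapse_carriers,
    fisher_exact_two_sided,
    fisher_midp_table,
    fisher_table_pvalues,
    run_exome_burden,
)
from exoburden.types import Consequence, ValidationError, VariantClass

from conftest import exact_fisher_oracle, make_variant


class TestFisherExact:
    def test_matches_enumeration_oracle_exhaustively_small(self):
        """Every 2x2 table with total <= 25 agrees with exact integer enumeration."""
        for n in range(1, 26):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    lo = max(0, c1 - (n - r1))
                    hi = min(r1, c1)
                    impl = fisher_table_pvalues(r1, n - r1, c1)
                    for a in range(lo, hi + 1):
                        b = r1 - a
                        c = c1 - a
                        d = n - r1 - c
                        expected = exact_fisher_oracle(a, b, c, d)
                        assert impl[a] == pytest.approx(expected, rel=1e-9)

    def test_three_table_example(self):
        # margins of (2,8,0,10) admit a=0,1,2; oracle gives 9/19
        assert fisher_exact_two_sided(2, 8, 0, 10) == pytest.approx(9 / 19, rel=1e-12)

    def test_discovery_scale_table(self):
        p = fisher_exact_two_sided(27, 1000, 0, 2733)
        assert p == pytest.approx(4.712425026e-16, rel=1e-8)

    def test_degenerate_margins_give_one(self):
        assert fisher_exact_two_sided(0, 10, 0, 20) == 1.0
        assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_scipy(self, a, b, c, d):
        """Independent cross-check against scipy's two-sided implementation."""
        if a + b + c + d == 0:
            return
        ours = fisher_exact_two_sided(a, b, c, d)
        theirs = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(theirs, rel=1e-9)

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(max_examples=150, deadline=None)
    def test_row_and_column_swap_invariance(self, a, b, c, d):
        p = fisher_exact_two_sided(a, b, c, d)
        assert fisher_exact_two_sided(c, d, a, b) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_two_sided(b, a, d, c) == pytest.approx(p, rel=1e-12)

    def test_monotone_evidence_with_zero_controls(self):
        """With fixed margins and no control carriers, more case carriers
        is never less significant."""
        n_cases, n_controls = 100, 200
        prev = 1.1
        for a in range(0, 20):
            p = fisher_exact_two_sided(a, n_cases - a, 0, n_controls)
            assert p <= prev + 1e-12
            prev = p

    def test_midp_below_p_and_valid(self):
        p = fisher_table_pvalues(50, 100, 10)
        midp = fisher_midp_table(50, 100, 10)
        sup = slice(0, 11)
        assert np.all(midp[sup] < p[sup])
        assert np.all(midp[sup] > 0)


class TestCollapseCarriers:
    def test_carrier_counted_once(self, small_cohort):
        variants = [
            make_variant("1:1:A:T", carriers=("CASE00001",)),
            make_variant("1:2:A:T", carriers=("CASE00001", "CTRL00003")),
        ]
        a, b, c, d = collapse_carriers("G1", VariantClass.LOF, variants, small_cohort)
        assert (a, b, c, d) == (1, 3, 1, 5)

    def test_empty_set_gives_zero_carriers(self, small_cohort):
        a, b, c, d = collapse_carriers("G1", VariantClass.LOF, [], small_cohort)
        assert (a, b, c, d) == (0, 4, 0, 6)

    def test_unknown_sample_rejected(self, small_cohort):
        variants = [make_variant("1:1:A:T", carriers=("NOT_A_SAMPLE",))]
        with pytest.raises(ValidationError, match="NOT_A_SAMPLE"):
            collapse_carriers("G1", VariantClass.LOF, variants, small_cohort)

    def test_qc_excluded_carriers_not_counted(self, small_cohort):
        small_cohort.exclude("CASE00001", "low_depth")
        variants = [make_variant("1:1:A:T", carriers=("CASE00001",))]
        a, b, c, d = collapse_carriers("G1", VariantClass.LOF, variants, small_cohort)
        assert (a, b) == (0, 3)


class TestExomeBurden:
    def test_bonferroni_threshold_at_study_scale(self):
        assert BurdenConfig().alpha / 19199 == pytest.approx(2.6e-6, rel=0.01)

    def test_single_gene_universe_threshold_is_alpha(self, small_cohort):
        qv = {("G1", VariantClass.LOF): [make_variant(carriers=("CASE00001",))]}
        results, G, threshold = run_exome_burden(qv, small_cohort)
        assert G == 1 and threshold == pytest.approx(0.05)

    def test_results_sorted_and_tie_broken(self, small_cohort):
        qv = {
            ("GB", VariantClass.LOF): [make_variant("1:1:A:T", carriers=("CASE00001",))],
            ("GA", VariantClass.LOF): [make_variant("1:2:A:T", carriers=("CASE00002",))],
        }
        results, _, _ = run_exome_burden(qv, small_cohort)
        assert [r.gene for r in results] == ["GA", "GB"]  # equal p, lex order

    def test_empty_universe_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            run_exome_burden({}, small_cohort)

    def test_case_control_label_swap_leaves_p_unchanged(self, small_cohort):
        qv = {
            ("G1", VariantClass.SYNONYMOUS): [
                make_variant("1:1:A:T", carriers=("CASE00001", "CTRL00001"))
            ]
        }
        results, _, _ = run_exome_burden(qv, small_cohort)
        flipped = CohortSwap(small_cohort)
        results2, _, _ = run_exome_burden(qv, flipped)
        assert results[0].p_value == pytest.approx(results2[0].p_value, rel=1e-12)


def CohortSwap(cohort):
    """Cohort with case/control labels exchanged."""
    from exoburden.types import CohortDesign, Sample

    return CohortDesign(
        [
            Sample(
                s.sample_id,
                "control" if s.status == "case" else "case",
                s.sex,
                s.cohort_label,
                s.mean_coding_depth,
            )
            for s in cohort.samples
        ]
    )
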