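"""Permutation-expected P values, inflation factor lambda, uniformity checks."""

from __future__ import annotations

import numpy as np
import pytest

from exoburden.burden import BurdenConfig, run_exome_burden
from exoburden.calibration import (
    PermutationConfig,
    calibrate,
    discreteness_adjusted_p,
    lambda_inflation,
    permutation_expected,
    uniformity_check,
)
from exoburden.lof import classify_variants
from exoburden.synthetic import SimulationConfig, generate_cohort
from exoburden.types import CohortDesign, Sample, ValidationError, VariantClass
from exoburden.variant_qc import select_qualifying_variants

from conftest import make_variant


def _small_qv_cohort(n_cases=30, n_controls=60, n_genes=8, seed=0):
    """Hand-rolled qv_sets + cohort small enough for brute-force re-runs."""
    rng = np.random.default_rng(seed)
    samples = [
        Sample(f"CASE{i:05d}", "case", "F", "c", 50.0) for i in range(1, n_cases + 1)
    ] + [
        Sample(f"CTRL{i:05d}", "control", "F", "c", 50.0)
        for i in range(1, n_controls + 1)
    ]
    cohort = CohortDesign(samples)
    ids = [s.sample_id for s in samples]
    qv_sets = {}
    for g in range(n_genes):
        n_car = int(rng.integers(1, 8))
        carriers = rng.choice(ids, size=n_car, replace=False)
        qv_sets[(f"G{g}", VariantClass.SYNONYMOUS)] = [
            make_variant(f"1:{g + 1}:A:T", gene=f"G{g}", carriers=tuple(carriers))
        ]
    return qv_sets, cohort


class TestPermutationExpected:
    def test_matches_full_rerun_of_relabeled_cohort(self):
        """The carrier-counting fast path is exact: a single permutation's
        expected P vector equals a fresh burden scan on the relabeled cohort."""
        qv_sets, cohort = _small_qv_cohort()
        seed = 123
        expected = permutation_expected(
            qv_sets, cohort, PermutationConfig(n_permutations=1, seed=seed)
        )
        # reproduce the single internal permutation and relabel the cohort
        rng = np.random.default_rng(seed)
        passing = cohort.passing()
        case_mask = np.array([s.status == "case" for s in passing], dtype=float)
        perm_mask = rng.permutation(case_mask)
        relabeled = CohortDesign(
            [
                Sample(s.sample_id, "case" if m else "control", s.sex, s.cohort_label,
                       s.mean_coding_depth)
                for s, m in zip(passing, perm_mask)
            ]
        )
        results, _, _ = run_exome_burden(qv_sets, relabeled)
        rerun = np.sort([r.p_value for r in results])
        assert expected[VariantClass.SYNONYMOUS] == pytest.approx(rerun, rel=1e-12)

    def test_deterministic_under_fixed_seed(self):
        qv_sets, cohort = _small_qv_cohort()
        cfg = PermutationConfig(n_permutations=20, seed=7)
        e1 = permutation_expected(qv_sets, cohort, cfg)
        e2 = permutation_expected(qv_sets, cohort, cfg)
        np.testing.assert_array_equal(
            e1[VariantClass.SYNONYMOUS], e2[VariantClass.SYNONYMOUS]
        )

    def test_invalid_permutation_count_rejected(self):
        with pytest.raises(ValidationError):
            PermutationConfig(n_permutations=0)

    def test_output_length_matches_observed_count(self):
        qv_sets, cohort = _small_qv_cohort(n_genes=5)
        expected = permutation_expected(
            qv_sets, cohort, PermutationConfig(n_permutations=3, seed=1)
        )
        assert len(expected[VariantClass.SYNONYMOUS]) == 5


class TestLambda:
    def test_identity_gives_unity(self):
        p = np.linspace(0.01, 0.99, 50)
        lam, n_exc = lambda_inflation(p, p, bonferroni_threshold=1e-6)
        assert lam == pytest.approx(1.0)
        assert n_exc == 0

    def test_exact_scaling_recovered(self):
        exp = np.linspace(0.01, 0.9, 50)
        obs = 10 ** (-1.2 * (-np.log10(exp)))  # -log10 obs = 1.2 * -log10 exp
        lam, _ = lambda_inflation(obs, exp, bonferroni_threshold=1e-12)
        assert lam == pytest.approx(1.2, rel=1e-9)

    def test_p_of_one_and_significant_hits_excluded(self):
        exp = np.array([1e-8, 0.01, 0.1, 0.5, 0.8])
        obs = np.array([1e-9, 0.01, 0.1, 0.5, 1.0])
        lam, n_exc = lambda_inflation(obs, exp, bonferroni_threshold=1e-6)
        assert n_exc == 2  # the 1e-9 hit and the exact 1.0
        assert lam == pytest.approx(1.0)

    def test_extreme_hit_barely_moves_lambda(self):
        """The exclusion rule shields lambda from true signal."""
        rng = np.random.default_rng(5)
        exp = np.sort(rng.uniform(0.001, 1, 500))
        obs = exp.copy()
        lam0, _ = lambda_inflation(obs, exp, bonferroni_threshold=1e-6)
        spiked = obs.copy()
        spiked[0] = 1e-16  # a planted-gene-like hit
        lam1, _ = lambda_inflation(np.sort(spiked), exp, bonferroni_threshold=1e-6)
        assert abs(lam1 - lam0) < 0.01

    def test_too_few_surviving_pairs_rejected(self):
        with pytest.raises(ValidationError):
            lambda_inflation([1.0, 1.0, 1e-9], [0.5, 0.9, 1e-8], 1e-6)

    def test_permutation_vs_permutation_centers_on_unity(self):
        """One permutation's P values treated as observed against the rest's
        expectation yield lambda near 1."""
        sim = generate_cohort(SimulationConfig(seed=21, n_genes=400))
        recs = classify_variants(sim.variants, sim.transcripts)
        sel = select_qualifying_variants(sim.variants, recs)
        obs = permutation_expected(
            sel.qv_sets, sim.cohort, PermutationConfig(1, seed=99)
        )
        exp = permutation_expected(
            sel.qv_sets, sim.cohort, PermutationConfig(50, seed=100)
        )
        cls = VariantClass.SYNONYMOUS
        lam, _ = lambda_inflation(obs[cls], exp[cls], bonferroni_threshold=1e-7)
        assert 0.8 < lam < 1.2


class TestCalibrateAndUniformity:
    def test_full_calibration_on_null_cohort(self):
        sim = generate_cohort(SimulationConfig(seed=31, n_genes=500))
        recs = classify_variants(sim.variants, sim.transcripts)
        sel = select_qualifying_variants(sim.variants, recs)
        results, G, thr = run_exome_burden(sel.qv_sets, sim.cohort)
        cal = calibrate(
            sel.qv_sets, sim.cohort, results, thr, PermutationConfig(40, seed=8)
        )
        assert {c.variant_class for c in cal} == set(BurdenConfig().classes)
        for c in cal:
            assert 0.8 < c.lambda_inflation < 1.2
            assert len(c.observed_p) == len(c.expected_p)

    def test_randomized_pit_is_uniform_under_null(self):
        sim = generate_cohort(SimulationConfig(seed=41, n_genes=600))
        recs = classify_variants(sim.variants, sim.transcripts)
        sel = select_qualifying_variants(sim.variants, recs)
        adj = discreteness_adjusted_p(
            sel.qv_sets, sim.cohort, rng=np.random.default_rng(77)
        )
        for cls, values in adj.items():
            ok, ks_p = uniformity_check(values, alpha=0.001)
            assert ok, f"{cls}: KS p={ks_p}"

    def test_midp_default_centers_on_half(self):
        sim = generate_cohort(SimulationConfig(seed=51, n_genes=300))
        recs = classify_variants(sim.variants, sim.transcripts)
        sel = select_qualifying_variants(sim.variants, recs)
        adj = discreteness_adjusted_p(sel.qv_sets, sim.cohort)
        pooled = np.concatenate(list(adj.values()))
        assert abs(pooled.mean() - 0.5) < 0.03
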