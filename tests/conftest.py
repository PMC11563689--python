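"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from exoburden.types import (
    AnnotatedVariant,
    CohortDesign,
    Consequence,
    GenotypeCall,
    Sample,
)


def exact_fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher P by exhaustive hypergeometric enumeration.

    Uses exact integer arithmetic (binomial coefficients), independent of
    the package's scipy-based implementation: sums the probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    nums = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    denom = math.comb(n, c1)
    obs = nums[a]
    return sum(x for x in nums.values() if x <= obs) / denom


def _binom_pmf(i: int, n: int, p: float) -> float:
    if p == 0.0:
        return 1.0 if i == 0 else 0.0
    if p == 1.0:
        return 1.0 if i == n else 0.0
    log_term = (
        math.lgamma(n + 1)
        - math.lgamma(i + 1)
        - math.lgamma(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
    )
    return math.exp(log_term)


def exact_binom_tail_le(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), by direct log-space summation."""
    return min(1.0, sum(_binom_pmf(i, n, p) for i in range(0, k + 1)))


def exact_binom_tail_ge(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    return max(0.0, 1.0 - exact_binom_tail_le(k - 1, n, p))


def clopper_pearson_bisection(k: int, n: int, ci_level: float = 0.95,
                              tol: float = 1e-12) -> tuple[float, float]:
    """Exact binomial CI by bisection on the binomial tail equations.

    Lower bound solves P(X >= k; p) = alpha/2, upper bound solves
    P(X <= k; p) = alpha/2; an independent oracle for the beta-quantile
    implementation.
    """
    alpha = 1 - ci_level

    def bisect(f, target, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    low = 0.0 if k == 0 else bisect(lambda p: exact_binom_tail_ge(k, n, p), alpha / 2, 0.0, 1.0)
    high = 1.0 if k == n else bisect(lambda p: -exact_binom_tail_le(k, n, p), -alpha / 2, 0.0, 1.0)
    return low, high


def make_variant(
    variant_id: str = "1:100:A:T",
    gene: str = "GENE0001",
    consequence: Consequence = Consequence.SYNONYMOUS,
    carriers: tuple[str, ...] = ("CASE00001",),
    mean_DP: float = 40.0,
    mean_QD: float = 20.0,
    mean_QUAL: float = 80.0,
    gq: float = 60.0,
    alt_fraction: float = 0.5,
    af_cases: float = 0.0001,
    af_controls: float = 0.0001,
    external: dict | None = None,
    predictor_flags: tuple | None = None,
    transcript_id: str = "TX0001",
    cds_ptc_position: int | None = None,
) -> AnnotatedVariant:
    """Build a valid variant with passing defaults; override what the test probes."""
    return AnnotatedVariant(
        variant_id=variant_id,
        gene=gene,
        transcript_id=transcript_id,
        consequence=consequence,
        predictor_flags=predictor_flags,
        mean_QD=mean_QD,
        mean_QUAL=mean_QUAL,
        mean_DP=mean_DP,
        internal_af_by_cohort={"cases": af_cases, "controls": af_controls},
        external_af_by_db=external or {},
        genotypes=[GenotypeCall(s, 1, 40, alt_fraction, gq) for s in carriers],
        cds_ptc_position=cds_ptc_position,
    )


@pytest.fixture
def small_cohort() -> CohortDesign:
    """10 samples: 4 cases, 6 controls, all with depth metadata."""
    samples = [
        Sample(f"CASE{i:05d}", "case", "F", "cohort1", 100.0 + i) for i in range(1, 5)
    ] + [
        Sample(f"CTRL{i:05d}", "control", "F", "controls", 90.0 + i)
        for i in range(1, 7)
    ]
    return CohortDesign(samples)
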