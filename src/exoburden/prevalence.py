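"""Carrier-prevalence estimation with exact binomial confidence intervals.

Carrier frequencies in case cohorts and population databases are binomial
proportions; at prevalences of ~1e-4 an exact (Clopper-Pearson) interval is
the defensible default, with the Wilson score interval available as an
option. Case-vs-population enrichment is summarized as a frequency ratio
with a two-sided Fisher exact P, and the carrier sex ratio is tested with a
two-sided exact binomial test.
"""

from __future__ import annotations

from typing import Sequence

from scipy import stats

from .burden import fisher_exact_two_sided
from .types import DatabaseCount, PrevalenceEstimate, ValidationError


def clopper_pearson_interval(k: int, n: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI by inverting the binomial tail tests (beta quantiles)."""
    if not 0 <= k <= n or n < 1:
        raise ValidationError("need 0 <= k <= n, n >= 1")
    alpha = 1.0 - ci_level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def wilson_interval(k: int, n: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (optional alternative to the exact interval)."""
    from statsmodels.stats.proportion import proportion_confint

    low, high = proportion_confint(k, n, alpha=1.0 - ci_level, method="wilson")
    return float(low), float(high)


def carrier_frequency(
    k: int,
    n: int,
    ci_level: float = 0.95,
    method: str = "clopper-pearson",
    source_label: str = "",
) -> PrevalenceEstimate:
    """Carrier frequency ``k / n`` with a binomial confidence interval."""
    if k > n:
        raise ValidationError(f"carriers ({k}) exceed denominator ({n})")
    if method == "clopper-pearson":
        low, high = clopper_pearson_interval(k, n, ci_level)
    elif method == "wilson":
        low, high = wilson_interval(k, n, ci_level)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    freq = k / n
    return PrevalenceEstimate(
        source_label=source_label,
        carriers=k,
        denominator=n,
        frequency=freq,
        ci_low=min(low, freq),
        ci_high=max(high, freq),
    )


def pooled_prevalence(
    database_counts: Sequence[DatabaseCount],
    ci_level: float = 0.95,
    method: str = "clopper-pearson",
) -> PrevalenceEstimate:
    """Accumulated prevalence over sources: pooled carriers over pooled n."""
    if not database_counts:
        raise ValidationError("no database counts provided")
    k = sum(c.carriers for c in database_counts)
    n = sum(c.denominator for c in database_counts)
    return carrier_frequency(k, n, ci_level, method, source_label="pooled")


def enrichment_ratio(
    case_estimate: PrevalenceEstimate, population_estimate: PrevalenceEstimate
) -> tuple[float, float]:
    """Case-vs-population carrier-frequency ratio and two-sided Fisher P."""
    if population_estimate.denominator == 0:
        raise ValidationError("population denominator is zero")
    if population_estimate.frequency == 0:
        raise ValidationError("population frequency is zero; ratio undefined")
    ratio = case_estimate.frequency / population_estimate.frequency
    p = fisher_exact_two_sided(
        case_estimate.carriers,
        case_estimate.denominator - case_estimate.carriers,
        population_estimate.carriers,
        population_estimate.denominator - population_estimate.carriers,
    )
    return ratio, p


def sex_ratio_test(k_female: int, k_male: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial P for the carrier sex split.

    Tests ``k_female`` successes in ``k_female + k_male`` trials against
    success probability ``p0`` (point-probability two-sided construction).
    """
    if k_female < 0 or k_male < 0:
        raise ValidationError("negative carrier counts")
    if k_female + k_male < 1:
        raise ValidationError("need at least one carrier")
    return float(stats.binomtest(k_female, k_female + k_male, p0).pvalue)
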