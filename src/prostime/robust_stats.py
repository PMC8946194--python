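"""Robust and nonparametric machinery for the estimation-bias analysis.

The chain is deliberately simple and fully reproducible: a Hodges-Lehmann
pseudomedian locates each estimate distribution; values deviating by more
than k (default 3) raw-sample standard deviations from the pseudomedian are
dropped in a single pass; variances of filtered statistics are obtained by
bootstrapping the *whole* process, filtering stage included; accuracy is
tested with one-sample Wilcoxon signed-rank tests (exact for small n) under
Bonferroni control; slopes are compared with z-tests; and per-block covariate
trends use ordinary least squares with t statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FilterResult",
    "BootstrapVariance",
    "WilcoxonResult",
    "TrendFit",
    "hodges_lehmann",
    "filter_outliers",
    "bootstrap_variance",
    "wilcoxon_signed_rank",
    "slope_z_test",
    "bonferroni",
    "block_trend_regression",
]


@dataclass
class FilterResult:
    """Outcome of the pseudomedian +/- k*SD outlier filter."""

    kept: np.ndarray
    removed: np.ndarray
    pseudomedian: float
    sd_used: float
    lower_bound: float
    upper_bound: float
    kept_mask: np.ndarray = field(repr=False, default=None)


@dataclass
class BootstrapVariance:
    """Bootstrap estimate of a filtered statistic and its uncertainty."""

    point_estimate: float
    se_of_estimate: float
    n_resamples: int
    seed: int | None
    n_redrawn: int = 0
    replicates: np.ndarray = field(repr=False, default=None)


@dataclass
class WilcoxonResult:
    """One-sample Wilcoxon signed-rank test result.

    statistic is V, the rank-sum of positive differences; method is one of
    "exact", "normal-approximation", "all-zero".
    """

    statistic: float
    n_effective: int
    p_value: float
    method: str


@dataclass
class TrendFit:
    """OLS fit of a covariate against block number."""

    slope: float
    intercept: float
    t_stat: float
    df: int
    p_value: float
    r_squared: float
    slope_se: float


def hodges_lehmann(sample: Sequence[float]) -> float:
    """Hodges-Lehmann pseudomedian: median of all Walsh averages
    (x_i + x_j) / 2 over i <= j (self-pairs included)."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("hodges_lehmann requires a non-empty sample")
    i, j = np.triu_indices(x.size)
    walsh = (x[i] + x[j]) / 2.0
    return float(np.median(walsh))


def filter_outliers(sample: Sequence[float], k: float = 3.0) -> FilterResult:
    """Single-pass outlier filter around the Hodges-Lehmann pseudomedian.

    The scale is the sample standard deviation (n-1 denominator) of the raw,
    unfiltered sample; values with |x - pseudomedian| strictly greater than
    k * SD are removed.  Samples of size < 2 pass through unchanged.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("filter_outliers requires a non-empty sample")
    if x.size < 2:
        return FilterResult(
            kept=x.copy(),
            removed=np.empty(0),
            pseudomedian=float(x[0]),
            sd_used=float("nan"),
            lower_bound=-math.inf,
            upper_bound=math.inf,
            kept_mask=np.ones(x.size, dtype=bool),
        )
    pm = hodges_lehmann(x)
    sd = float(np.std(x, ddof=1))
    lo, hi = pm - k * sd, pm + k * sd
    mask = np.abs(x - pm) <= k * sd
    return FilterResult(
        kept=x[mask],
        removed=x[~mask],
        pseudomedian=pm,
        sd_used=sd,
        lower_bound=lo,
        upper_bound=hi,
        kept_mask=mask,
    )


def _sample_variance(values: np.ndarray) -> float:
    return float(np.var(values, ddof=1))


def bootstrap_variance(
    sample: Sequence[float],
    B: int = 1000,
    seed: int | None = None,
    k: float = 3.0,
    statistic: Callable[[np.ndarray], float] | None = None,
    max_redraws: int = 10_000,
) -> BootstrapVariance:
    """Bootstrap a filtered statistic (default: sample variance after the
    outlier filter), resampling the *raw* sample so the filtering stage is
    inside the bootstrap loop.

    Resamples whose filtered size falls below 2 are redrawn and counted.
    """
    x = np.asarray(sample, dtype=float)
    if B < 100:
        raise ValueError("B must be >= 100")
    if x.size < 2:
        raise ValueError("bootstrap_variance requires a sample of size >= 2")
    if statistic is None:
        statistic = _sample_variance
    rng = np.random.default_rng(seed)

    base_kept = filter_outliers(x, k).kept
    point = statistic(base_kept) if base_kept.size >= 2 else float("nan")
    replicates = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            resample = rng.choice(x, size=x.size, replace=True)
            kept = filter_outliers(resample, k).kept
            if kept.size >= 2:
                break
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("bootstrap: too many degenerate resamples")
        replicates[b] = statistic(kept)
    return BootstrapVariance(
        point_estimate=point,
        se_of_estimate=float(np.std(replicates, ddof=1)),
        n_resamples=B,
        seed=seed,
        n_redrawn=n_redrawn,
        replicates=replicates,
    )


def _exact_two_sided_p(ranks: np.ndarray, v: float) -> float:
    # Distribution of V under random sign flips, by convolution over the
    # doubled (hence integer) rank values; equivalent to enumerating all
    # 2^n sign assignments.
    scaled = np.rint(2 * ranks).astype(np.int64)
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for s in scaled:
        shifted = np.zeros_like(counts)
        shifted[s:] = counts[: total + 1 - s]
        counts += shifted
    n_total = counts.sum()  # 2**n
    v2 = int(round(2 * v))
    lower = counts[: v2 + 1].sum() / n_total
    upper = counts[v2:].sum() / n_total
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    sample: Sequence[float], mu0: float = 0.0, exact_threshold: int = 25
) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu0``.

    Zero differences are dropped; tied absolute differences get average
    ranks.  The p-value is exact (full sign-assignment distribution) when the
    effective n is <= ``exact_threshold``, otherwise a tie-corrected,
    continuity-corrected normal approximation is used.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("wilcoxon_signed_rank requires a non-empty sample")
    d = x - mu0
    d = d[d != 0]
    n = d.size
    if n == 0:
        m = x.size
        return WilcoxonResult(
            statistic=m * (m + 1) / 4.0, n_effective=0, p_value=1.0, method="all-zero"
        )
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())

    if n <= exact_threshold:
        p = _exact_two_sided_p(ranks, v)
        return WilcoxonResult(statistic=v, n_effective=n, p_value=p, method="exact")

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return WilcoxonResult(statistic=v, n_effective=n, p_value=1.0, method="normal-approximation")
    # continuity correction toward the mean
    z = (v - mu - 0.5 * np.sign(v - mu)) / math.sqrt(sigma2)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(statistic=v, n_effective=n, p_value=p, method="normal-approximation")


def slope_z_test(
    b1: float, se1: float, b2: float = 0.0, se2: float = 0.0
) -> tuple[float, float]:
    """z-test for the difference of two slopes (or one slope against zero).

    z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided normal p.
    """
    denom2 = se1**2 + se2**2
    if denom2 <= 0:
        raise ValueError("slope_z_test requires se1^2 + se2^2 > 0")
    z = (b1 - b2) / math.sqrt(denom2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) with m the family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)


def block_trend_regression(
    block_index: Sequence[float], values: Sequence[float]
) -> TrendFit:
    """OLS of a covariate on block number; t = slope / SE(slope), df = n - 2.

    A perfect non-flat fit reports t = +/-inf (p = 0); a perfectly flat
    response reports t = 0 (p = 1).
    """
    x = np.asarray(block_index, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise ValueError("block_index and values must have the same length")
    if x.size < 3:
        raise ValueError("block_trend_regression requires >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all block indices are equal")

    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    rss = float((resid**2).sum())
    tss = float(((y - ybar) ** 2).sum())
    df = x.size - 2
    se = math.sqrt(max(rss, 0.0) / df / sxx) if df > 0 else float("nan")
    perfect = rss <= 1e-12 * (tss if tss > 0 else 1.0)
    if se == 0 or perfect:
        if math.isclose(slope, 0.0, abs_tol=1e-12):
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, slope), 0.0
    else:
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return TrendFit(slope, intercept, t, df, p, r2, se)
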