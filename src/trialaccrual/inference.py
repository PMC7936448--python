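"""Recruitment-rate estimation and a chi-squared check of the Poisson model.

The accrual model treats a site's per-period recruitment counts as iid
Poisson.  Monitoring needs two inferential pieces: the maximum-likelihood
rate (the mean count over the site's active window, zero periods included)
and a goodness-of-fit test of the Poisson assumption itself — a classic
chi-squared comparison of the histogram of per-period counts against the
Poisson pmf with its mean estimated from the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (DegenerateDataError, InsufficientDataError, NoDataError,
                    PeriodCounts)


@dataclass(frozen=True)
class RateEstimate:
    """MLE of a site's recruitment rate over an observation window."""

    site_id: str
    rate_hat: float
    n_periods: int
    n_recruits: int


@dataclass(frozen=True)
class GofBin:
    """One (possibly merged) count category of the chi-squared table.

    ``hi`` is inclusive; ``None`` marks the open-ended upper tail (>= lo).
    """

    lo: int
    hi: int | None
    observed: int
    expected: float

    @property
    def label(self) -> str:
        if self.hi is None:
            return f">={self.lo}"
        if self.hi == self.lo:
            return str(self.lo)
        return f"{self.lo}-{self.hi}"


@dataclass(frozen=True)
class GofResult:
    """Chi-squared Poisson goodness-of-fit outcome for one site."""

    statistic: float
    df: int
    p_value: float
    bins: tuple[GofBin, ...]
    rate_hat: float
    n_periods: int


def estimate_rate(counts: PeriodCounts, through_period: int | None = None,
                  from_period: int | None = None) -> RateEstimate:
    """Mean recruitments per period over the site's active window.

    The window runs from ``from_period`` (default: the site's first active
    period) through ``through_period`` (default: the last period of the
    counts vector), inclusive; zero-count periods inside the window count
    toward the denominator.  Estimating from the first *recorded* activity
    rather than period 1 avoids penalising a site for its initiation delay.
    """
    start = from_period if from_period is not None else counts.first_active_period
    if start is None:
        raise NoDataError(f"site {counts.site_id!r} has no recorded activity")
    if start < 1:
        raise ValueError(f"from_period must be >= 1, got {start}")
    end = through_period if through_period is not None else counts.n_periods
    if end < start:
        raise ValueError(
            f"empty estimation window: through_period {end} < from_period {start}")
    window = counts.counts[start - 1:end]
    n_periods = end - start + 1
    n_recruits = int(sum(window))
    return RateEstimate(site_id=counts.site_id, rate_hat=n_recruits / n_periods,
                        n_periods=n_periods, n_recruits=n_recruits)


def _initial_bins(observed_hist: np.ndarray, rate_hat: float,
                  n: int) -> list[GofBin]:
    """Singleton categories 0..K-1 plus an open tail >= K, K the max count."""
    k_max = len(observed_hist) - 1  # largest observed count
    bins = []
    for k in range(k_max):
        bins.append(GofBin(lo=k, hi=k, observed=int(observed_hist[k]),
                           expected=n * float(stats.poisson.pmf(k, rate_hat))))
    # survival function keeps the expected column summing exactly to n
    bins.append(GofBin(lo=k_max, hi=None, observed=int(observed_hist[k_max]),
                       expected=n * float(stats.poisson.sf(k_max - 1, rate_hat))))
    return bins


def _merge(a: GofBin, b: GofBin) -> GofBin:
    return GofBin(lo=min(a.lo, b.lo),
                  hi=None if a.hi is None or b.hi is None else max(a.hi, b.hi),
                  observed=a.observed + b.observed,
                  expected=a.expected + b.expected)


def _merge_bins(bins: list[GofBin], min_expected: float) -> list[GofBin]:
    """Merge adjacent categories, tails first, until all expected >= min_expected."""
    bins = list(bins)
    while len(bins) > 1:
        if bins[0].expected < min_expected:
            bins[:2] = [_merge(bins[0], bins[1])]
        elif bins[-1].expected < min_expected:
            bins[-2:] = [_merge(bins[-2], bins[-1])]
        else:
            deficient = [i for i, b in enumerate(bins) if b.expected < min_expected]
            if not deficient:
                break
            i = deficient[0]  # interior bin: fold into its left neighbour
            bins[i - 1:i + 1] = [_merge(bins[i - 1], bins[i])]
    return bins


def poisson_gof(counts: PeriodCounts, min_expected: float = 5.0) -> GofResult:
    """Chi-squared goodness-of-fit of per-period counts to a Poisson law.

    Fits the Poisson mean by the sample mean of the counts, tabulates
    observed frequencies of each count value k = 0, 1, 2, ... (the last
    category open-ended via the survival function so expected frequencies
    total exactly ``n_periods``), merges adjacent categories from both tails
    until every expected frequency is at least ``min_expected``, and refers
    sum (obs - exp)^2 / exp to chi-squared with df = (bins - 2): one degree
    for the fixed total and one for the estimated mean.

    Raises
    ------
    DegenerateDataError
        All counts are zero, so the fitted mean is 0 and the test is vacuous.
    InsufficientDataError
        Fewer than 3 categories survive merging (df would be < 1).
    """
    if min_expected <= 0:
        raise ValueError(f"min_expected must be > 0, got {min_expected}")
    data = np.asarray(counts.counts, dtype=np.int64)
    if data.size == 0:
        raise InsufficientDataError(f"site {counts.site_id!r}: no periods to test")
    rate_hat = float(data.mean())
    if rate_hat == 0.0:
        raise DegenerateDataError(
            f"site {counts.site_id!r}: all per-period counts are zero")
    hist = np.bincount(data)
    bins = _merge_bins(_initial_bins(hist, rate_hat, data.size), min_expected)
    if len(bins) < 3:
        raise InsufficientDataError(
            f"site {counts.site_id!r}: only {len(bins)} count categories have "
            f"expected frequency >= {min_expected}; chi-squared test not computable")
    obs = np.array([b.observed for b in bins], dtype=float)
    exp = np.array([b.expected for b in bins], dtype=float)
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = len(bins) - 2
    p_value = float(stats.chi2.sf(statistic, df))
    return GofResult(statistic=statistic, df=df, p_value=p_value,
                     bins=tuple(bins), rate_hat=rate_hat, n_periods=int(data.size))
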