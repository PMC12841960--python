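"""Nonparametric method-comparison statistics for paired fHb measurements.

Implements the statistics used to compare the Harboe spectrophotometric
method (reference, x) against the analyzer hemolysis-index estimate
(comparator, y):

* Passing-Bablok regression: the slope is the shifted median of all
  pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i), i < j, after excluding
  undefined pairs (both coordinates tied) and slopes exactly equal to -1;
  the offset K (number of slopes < -1) shifts the median rank so the
  estimator is invariant under swapping the axes.  Confidence intervals
  use the analytical rank method with half-width
  w = z * sqrt(n (n - 1) (2 n + 5) / 18).
* Bland-Altman agreement: differences are taken as d = x - y (reference
  minus comparator), so a comparator that underestimates yields a positive
  bias.  Limits of agreement are bias +/- 1.96 * SD (sample SD, n - 1);
  the bias CI uses the t distribution.
* Spearman rank correlation with average ranks for ties, a Fisher-z
  confidence interval (SD 1/sqrt(n - 3)) and the t-approximation p-value.

These are deliberately authored here rather than delegated: the pairwise
slope enumeration with the K-offset is the substance under test, and the
test suite cross-checks it against independent brute-force enumeration and
against library rank-correlation routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EstimationError",
    "PairedMeasurements",
    "ConfidenceInterval",
    "PassingBablokResult",
    "BlandAltmanResult",
    "SpearmanResult",
    "ComparisonResult",
    "passing_bablok",
    "bland_altman",
    "spearman",
    "compare_methods",
]

#: Sign convention for all difference-based quantities.
DIFFERENCE_DIRECTION = "reference_minus_comparator (fHb - efHb)"

#: Below this sample size, rank-based confidence intervals are unreliable
#: and are reported as None.
MIN_N_FOR_CI = 10


class EstimationError(ValueError):
    """Raised when the data are too degenerate for an estimate."""


@dataclass(frozen=True)
class ConfidenceInterval:
    low: float
    high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"CI bounds out of order: ({self.low}, {self.high})")

    def covers(self, value: float) -> bool:
        return self.low <= value <= self.high


class PairedMeasurements:
    """Paired (reference, comparator) measurements in mg/L.

    ``x`` is the reference method (Harboe fHb), ``y`` the comparator
    (index-estimated efHb).  Requires equal lengths, finite values and
    n >= 3.
    """

    def __init__(self, x: Sequence[float], y: Sequence[float]):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if len(x) != len(y):
            raise ValueError(f"length mismatch: len(x)={len(x)}, len(y)={len(y)}")
        if len(x) < 3:
            raise ValueError(f"need at least 3 pairs, got {len(x)}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("x and y must be finite")
        self.x = x
        self.y = y

    @property
    def n(self) -> int:
        return len(self.x)

    def swapped(self) -> "PairedMeasurements":
        return PairedMeasurements(self.y, self.x)


@dataclass(frozen=True)
class PassingBablokResult:
    slope: float
    intercept: float
    slope_ci: Optional[ConfidenceInterval]
    intercept_ci: Optional[ConfidenceInterval]
    n: int
    n_slopes: int  # valid pairwise slopes after exclusions
    ci_level: float = 0.95


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    bias_ci: ConfidenceInterval
    loa_low: float
    loa_high: float
    sd: float
    loa_multiplier: float
    n: int
    difference_direction: str = DIFFERENCE_DIRECTION


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci: Optional[ConfidenceInterval]
    p_value: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    """Bundle of all method-comparison outputs for one paired dataset."""

    passing_bablok: PassingBablokResult
    bland_altman: BlandAltmanResult
    spearman: SpearmanResult
    n: int
    difference_direction: str = DIFFERENCE_DIRECTION


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """All valid pairwise slopes, sorted ascending, plus the offset K.

    Pairs with both coordinates tied are undefined and dropped; x-ties with
    unequal y contribute +/-inf slopes (counted at the extremes); slopes
    exactly -1 are excluded.  K counts slopes < -1 (including -inf).
    """
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0.0) & (dy == 0.0))
    dx, dy = dx[keep], dy[keep]
    with np.errstate(divide="ignore"):
        slopes = np.where(dx != 0.0, dy / np.where(dx == 0.0, 1.0, dx), np.where(dy > 0, np.inf, -np.inf))
    slopes = slopes[slopes != -1.0]
    slopes.sort()
    K = int(np.sum(slopes < -1.0))
    return slopes, K


def _shifted_median(sorted_slopes: np.ndarray, K: int) -> float:
    N = len(sorted_slopes)
    if N % 2:
        return float(sorted_slopes[(N + 1) // 2 + K - 1])
    return float(
        0.5 * (sorted_slopes[N // 2 + K - 1] + sorted_slopes[N // 2 + K])
    )


def passing_bablok(
    data: PairedMeasurements, ci_level: float = 0.95
) -> PassingBablokResult:
    """Passing-Bablok regression of comparator on reference.

    Returns slope and intercept with analytical rank-based confidence
    intervals (``None`` for n < 10).  Raises :class:`EstimationError` when
    every pairwise slope is excluded (e.g. all points identical).
    """
    x, y, n = data.x, data.y, data.n
    slopes, K = _pairwise_slopes(x, y)
    if len(slopes) == 0:
        raise EstimationError("degenerate data: no valid pairwise slopes")
    b = _shifted_median(slopes, K)
    if not np.isfinite(b):
        raise EstimationError("degenerate data: median pairwise slope is infinite")
    a = float(np.median(y - b * x))

    slope_ci = intercept_ci = None
    if n >= MIN_N_FOR_CI:
        N = len(slopes)
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        w = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
        m1 = int(round((N - w) / 2.0))
        m2 = N - m1 + 1
        lo_idx = min(max(m1 + K - 1, 0), N - 1)
        hi_idx = min(max(m2 + K - 1, 0), N - 1)
        b_low = float(slopes[lo_idx])
        b_high = float(slopes[hi_idx])
        slope_ci = ConfidenceInterval(b_low, b_high, ci_level)
        # A larger slope pulls the median intercept down, so the intercept
        # bounds come from the opposite slope bounds.
        intercept_ci = ConfidenceInterval(
            float(np.median(y - b_high * x)),
            float(np.median(y - b_low * x)),
            ci_level,
        )
    return PassingBablokResult(
        slope=b,
        intercept=a,
        slope_ci=slope_ci,
        intercept_ci=intercept_ci,
        n=n,
        n_slopes=len(slopes),
        ci_level=ci_level,
    )


def bland_altman(
    data: PairedMeasurements,
    loa_multiplier: float = 1.96,
    ci_level: float = 0.95,
) -> BlandAltmanResult:
    """Bland-Altman agreement of the two methods.

    Differences are reference minus comparator; the bias is their mean,
    the limits of agreement bias +/- ``loa_multiplier`` * SD.
    """
    d = data.x - data.y
    n = data.n
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = loa_multiplier * sd
    t = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    se = sd / math.sqrt(n)
    return BlandAltmanResult(
        bias=bias,
        bias_ci=ConfidenceInterval(bias - t * se, bias + t * se, ci_level),
        loa_low=bias - half,
        loa_high=bias + half,
        sd=sd,
        loa_multiplier=loa_multiplier,
        n=n,
    )


def spearman(data: PairedMeasurements, ci_level: float = 0.95) -> SpearmanResult:
    """Spearman rank correlation with Fisher-z CI and t-approximation p."""
    rx = stats.rankdata(data.x)  # average ranks for ties
    ry = stats.rankdata(data.y)
    if np.std(rx) == 0.0 or np.std(ry) == 0.0:
        raise EstimationError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = data.n

    if abs(rho) >= 1.0:
        p_value = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p_value = float(2.0 * stats.t.sf(abs(t), df=n - 2))

    ci = None
    if n >= MIN_N_FOR_CI and abs(rho) < 1.0:
        z = math.atanh(rho)
        zc = stats.norm.ppf(0.5 + ci_level / 2.0)
        half = zc / math.sqrt(n - 3)
        ci = ConfidenceInterval(math.tanh(z - half), math.tanh(z + half), ci_level)
    return SpearmanResult(rho=rho, ci=ci, p_value=p_value, n=n)


def compare_methods(
    data: PairedMeasurements,
    ci_level: float = 0.95,
    loa_multiplier: float = 1.96,
) -> ComparisonResult:
    """Full method comparison: regression, agreement and correlation."""
    return ComparisonResult(
        passing_bablok=passing_bablok(data, ci_level=ci_level),
        bland_altman=bland_altman(data, loa_multiplier=loa_multiplier, ci_level=ci_level),
        spearman=spearman(data, ci_level=ci_level),
        n=data.n,
    )
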