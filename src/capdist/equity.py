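"""Equity analytics for commuting times: Lorenz curves, Gini coefficients,
time summaries, threshold counts and rank-sum group comparison.

The Gini coefficient here is the classical Lorenz-geometric one: patients
are ranked by commuting time, the cumulative share of total time is plotted
against the cumulative share of patients, and the coefficient is the area
between that polyline and the diagonal divided by the triangle under the
diagonal.  Algebraically this equals sum_ij |x_i - x_j| / (2 n^2 mean); no
small-sample correction is applied.  Zero times are legal observations; only
an all-zero vector is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LorenzCurve",
    "TimeSummary",
    "RankSumResult",
    "DegenerateCurveError",
    "lorenz",
    "gini",
    "summarize_times",
    "threshold_counts",
    "rank_sum_test",
    "relative_change",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (30.0, 45.0, 60.0, 90.0)


class DegenerateCurveError(ValueError):
    """Lorenz curve / Gini are undefined (all observations zero)."""


def _validate(times) -> np.ndarray:
    x = np.asarray(times, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("at least one observation is required")
    if not np.isfinite(x).all() or (x < 0).any():
        raise ValueError("times must be finite and non-negative")
    return x


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative patient share vs cumulative time share, (n+1) points from
    (0, 0) to (1, 1); lies on or below the diagonal."""

    points: np.ndarray  # shape (n+1, 2)

    @property
    def patient_share(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def time_share(self) -> np.ndarray:
        return self.points[:, 1]


def lorenz(times) -> LorenzCurve:
    """Lorenz curve of commuting times: sort ascending, point k is
    (k/n, sum of k smallest / total)."""
    x = np.sort(_validate(times))
    total = x.sum()
    if total == 0:
        raise DegenerateCurveError("all times are zero; time shares undefined")
    n = x.size
    pts = np.empty((n + 1, 2))
    pts[:, 0] = np.arange(n + 1) / n
    pts[0, 1] = 0.0
    pts[1:, 1] = np.cumsum(x) / total
    return LorenzCurve(points=pts)


def gini(times) -> float:
    """Gini coefficient via the trapezoidal area between the Lorenz
    polyline and the diagonal, normalised by the half-unit triangle.

    Equals sum_i sum_j |x_i - x_j| / (2 n^2 mean); 0 iff all times equal,
    always < 1 - 1/n.
    """
    curve = lorenz(times)
    y = curve.time_share
    n = y.size - 1
    area_under = float(np.sum((y[1:] + y[:-1]) / 2.0)) / n
    return 1.0 - 2.0 * area_under


@dataclass(frozen=True)
class TimeSummary:
    """Five-number commuting-time summary (minutes)."""

    n: int
    median: float
    q25: float
    q75: float
    min: float
    max: float


def summarize_times(times) -> TimeSummary:
    """Median, interquartile range and range, with linearly interpolated
    quantiles."""
    x = _validate(times)
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    return TimeSummary(
        n=x.size, median=float(med), q25=float(q25), q75=float(q75),
        min=float(x.min()), max=float(x.max()),
    )


def threshold_counts(
    times, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> dict[float, int]:
    """Number of patients with commuting time strictly greater than each
    threshold ("longer than" is strict: exactly 30 min does not count as
    > 30)."""
    x = _validate(times)
    return {float(th): int((x > th).sum()) for th in thresholds}


@dataclass(frozen=True)
class RankSumResult:
    u: float  # Mann-Whitney U of group A
    p: float  # two-sided
    method: str  # "exact" | "asymptotic"


def rank_sum_test(group_a, group_b) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum comparison of two time samples.

    Uses the exact null distribution when both groups have n <= 8 and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    and continuity corrections.
    """
    a = _validate(group_a)
    b = _validate(group_b)
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    exact = a.size <= 8 and b.size <= 8 and tie_free
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return RankSumResult(
        u=float(res.statistic), p=float(res.pvalue),
        method="exact" if exact else "asymptotic",
    )


def relative_change(baseline: float, scenario: float) -> float:
    """Signed percent change 100 * (scenario - baseline) / baseline;
    round to integer percent for report display."""
    if baseline == 0:
        raise ValueError("relative change undefined for a zero baseline")
    return 100.0 * (scenario - baseline) / baseline
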