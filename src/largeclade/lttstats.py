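"""Lineage-through-time diagnostics.

An LTT curve counts the ancestral lineages of the extant sample back through
time; for a typical Yule clade it is a straight line of slope ``lam`` on a
semi-log plot.  Clades conditioned to be unusually large show an early excess
of branching (a "bulge" above that line) and unusually small ones a deficit —
the tree-shape signature that misleads both naive extrapolation and the tree
prior of a Bayesian dating analysis.

The lineage-production-rate series is a finer-grained diagnostic: each
inter-branching interval with k extant lineages and duration dt contributes
one point ``1 / (k * dt)`` — the inverse of the total branch length laid down
between successive lineage creations — optionally smoothed with a centred
moving average in age units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cladesize import naive_extrapolated_origin  # noqa: F401  (re-export companion)
from .trees import UltrametricTree

__all__ = [
    "LTTCurve",
    "RateSeries",
    "ltt",
    "semilog_slope",
    "lineage_production_rate",
    "naive_origin_from_ltt",
]


@dataclass
class LTTCurve:
    """Branching ages (Myr before present, descending) and lineage counts.

    ``counts[i]`` is the number of lineages immediately after the branching
    at ``ages[i]``; the curve starts at the root (count 2 for a crown tree)
    and ends at the tip count.
    """

    ages: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.ages.shape != self.counts.shape:
            raise ValueError("ages and counts must have equal length")
        if np.any(np.diff(self.ages) > 0):
            raise ValueError("ages must be non-increasing")

    def count_at(self, age) -> np.ndarray | int:
        """Lineage count crossing a given age (vectorized)."""
        idx = np.searchsorted(-self.ages, -np.asarray(age, dtype=float), side="right")
        counts = np.concatenate([[self.counts[0] - 1 or 1], self.counts])
        out = counts[idx]
        return int(out) if np.ndim(age) == 0 else out


def ltt(tree: UltrametricTree) -> LTTCurve:
    """LTT curve of an ultrametric tree (counts of lineages per branching)."""
    ages = np.sort(tree.ages[tree.n_tips :])[::-1]
    start = 2 if tree.origin_age is None else 1
    counts = np.arange(start, start + len(ages))
    return LTTCurve(ages, counts)


def semilog_slope(curve: LTTCurve, age_window: tuple[float, float]) -> float:
    """Least-squares slope of log(count) against time within an age window.

    The slope is positive for growth toward the present and estimates the
    diversification rate on the straight section of a Yule clade's curve.
    """
    lo, hi = min(age_window), max(age_window)
    mask = (curve.ages >= lo) & (curve.ages <= hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 branchings in the fit window")
    # regress on -age so that growth toward the present is a positive slope
    b, _ = np.polyfit(-curve.ages[mask], np.log(curve.counts[mask]), 1)
    return float(b)


@dataclass
class RateSeries:
    """Per-interval lineage-production rates, with an optional smoothed track."""

    ages: np.ndarray  # interval midpoints, Myr before present
    rates: np.ndarray  # 1 / (k * dt) per inter-branching interval
    smoothed: np.ndarray
    window: float


def lineage_production_rate(tree: UltrametricTree, smooth_window: float = 50.0) -> RateSeries:
    """Inverse total branch length between successive lineage creations.

    Between branchings at ages ``a_i > a_{i+1}`` with k extant lineages the
    tree lays down ``k * (a_i - a_{i+1})`` Myr of branch; the interval's rate
    point is the reciprocal, placed at the interval midpoint.  Zero-length
    intervals (simultaneous branchings) are skipped.  ``smooth_window`` is
    the full width (Myr) of a centred window within which the smoothed value
    is events per unit branch length (the harmonic-style mean of the raw
    points, which individually have a heavy upper tail); 0 disables
    smoothing.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips for a rate series")
    curve = ltt(tree)
    dt = curve.ages[:-1] - curve.ages[1:]
    keep = dt > 0
    k = curve.counts[:-1][keep]
    mid = 0.5 * (curve.ages[:-1] + curve.ages[1:])[keep]
    rates = 1.0 / (k * dt[keep])
    if smooth_window > 0:
        # windowed rate = events / total branch length laid down in the
        # window — the harmonic-style average of the raw points, immune to
        # the heavy tail of individual 1/(k*dt) values
        half = smooth_window / 2.0
        blen = k * dt[keep]
        smoothed = np.empty_like(rates)
        for i, a in enumerate(mid):
            w = np.abs(mid - a) <= half
            smoothed[i] = w.sum() / blen[w].sum()
    else:
        smoothed = rates.copy()
    return RateSeries(mid, rates, smoothed, float(smooth_window))


def naive_origin_from_ltt(
    curve: LTTCurve, fit_window: tuple[float, float] | None = None
) -> float:
    """Clade origin implied by extrapolating the semi-log LTT back to 1 lineage.

    Fits log(count) against age over ``fit_window`` (default: the middle 60%
    of the curve's age span, avoiding the root bulge and the near-present
    flattening) and solves for the age at which the fitted line reaches a
    single lineage.  With a noiseless exponential curve this reproduces
    ``ln(N) / lam`` exactly.
    """
    root = curve.ages[0]
    if fit_window is None:
        fit_window = (0.2 * root, 0.8 * root)
    lo, hi = min(fit_window), max(fit_window)
    mask = (curve.ages >= lo) & (curve.ages <= hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 branchings in the fit window")
    slope, intercept = np.polyfit(curve.ages[mask], np.log(curve.counts[mask]), 1)
    if slope >= 0:
        raise ValueError("degenerate fit: lineage count does not grow toward the present")
    # log(count) = intercept + slope * age; count = 1 at age -intercept/slope...
    return float(-intercept / slope)
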