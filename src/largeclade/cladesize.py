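"""Analytic clade-size distributions under the Yule process.

A Yule clade of age ``T`` and birth rate ``lam`` founded by a single lineage
has a geometrically distributed extant size with success parameter
``p = exp(-lam * T)`` (mean ``1/p``); a crown clade, being the sum of its two
root lineages' clades, is negative binomial with two successes (mean ``2/p``).
These distributions are heavily right-skewed: the mean is well above the
median, most clades are smaller than "expected", and a non-trivial fraction
are several times too large — the raw material of the large clade effect.

Also here: the naive estimator that extrapolates a clade's origin from its
present size and background diversification rate, ``ln(N) / lam``; applied to
a clade that is ``alpha`` times its expected size, it overshoots the true
origin by ``ln(alpha) / lam``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CladeSizeModel",
    "RelativeSizeQuery",
    "clade_size_pmf",
    "clade_size_survival",
    "prob_relative_size",
    "naive_extrapolated_origin",
    "section_summary",
]


@dataclass(frozen=True)
class CladeSizeModel:
    """Size distribution of a Yule clade of fixed age.

    ``n_founders`` is 1 (geometric) or 2 (negative binomial, two successes);
    ``p = exp(-birth_rate * age)`` is the per-founder success parameter and
    the mean size is ``n_founders / p``.
    """

    n_founders: int
    p: float

    def __post_init__(self) -> None:
        if self.n_founders not in (1, 2):
            raise ValueError("n_founders must be 1 or 2")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")

    @property
    def mean(self) -> float:
        return self.n_founders / self.p

    @classmethod
    def from_rate_age(cls, birth_rate: float, age: float, n_founders: int = 2) -> "CladeSizeModel":
        return cls(n_founders, math.exp(-birth_rate * age))

    @classmethod
    def from_mean(cls, mean: float, n_founders: int = 2) -> "CladeSizeModel":
        if mean < n_founders:
            raise ValueError("mean must be at least n_founders")
        return cls(n_founders, n_founders / mean)


@dataclass(frozen=True)
class RelativeSizeQuery:
    """A window of clade sizes expressed as multiples of the mean."""

    lo_mult: float
    hi_mult: float = math.inf

    def __post_init__(self) -> None:
        if not 0 <= self.lo_mult < self.hi_mult:
            raise ValueError("need 0 <= lo_mult < hi_mult")


def clade_size_pmf(model: CladeSizeModel, n) -> np.ndarray | float:
    """P(clade size = n): geometric (f=1) or two-success negative binomial (f=2)."""
    n = np.asarray(n)
    if np.any(n < model.n_founders):
        raise ValueError("n must be at least n_founders")
    out = stats.nbinom.pmf(n - model.n_founders, model.n_founders, model.p)
    return float(out) if out.ndim == 0 else out


def clade_size_survival(model: CladeSizeModel, n: int) -> float:
    """P(clade size >= n), in closed form.

    f=1: ``q^(n-1)``;  f=2: ``q^(n-2) * (q + (n-1) p)`` with ``q = 1 - p``.
    """
    if n <= model.n_founders:
        return 1.0
    p, q = model.p, 1.0 - model.p
    if model.n_founders == 1:
        return float(q ** (n - 1))
    return float(q ** (n - 2) * (q + (n - 1) * p))


def prob_relative_size(model: CladeSizeModel, query: RelativeSizeQuery) -> float:
    """Probability the clade size lies within a window of multiples of its mean.

    Integer bounds are inclusive: ``ceil(lo_mult * mean)`` up to
    ``floor(hi_mult * mean)`` (or the upper tail when unbounded).
    """
    lo = max(model.n_founders, math.ceil(query.lo_mult * model.mean))
    if math.isinf(query.hi_mult):
        return clade_size_survival(model, lo)
    hi = math.floor(query.hi_mult * model.mean)
    if hi < lo:
        return 0.0
    return clade_size_survival(model, lo) - clade_size_survival(model, hi + 1)


def naive_extrapolated_origin(n_observed: float, birth_rate: float) -> float:
    """Clade origin implied by extrapolating steady Yule growth: ``ln(N)/lam``.

    The single-founder convention: a clade observed at ``N`` species with
    background rate ``lam`` "should" have taken ``ln(N)/lam`` Myr to grow.
    """
    if n_observed < 1:
        raise ValueError("n_observed must be at least 1")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    return float(np.log(n_observed) / birth_rate)


def section_summary(model: CladeSizeModel) -> dict[str, float]:
    """Reference relative-size probabilities for a clade-size model.

    Windows: within [0.5x, 2x] of the mean; at least 2x; at least 3x;
    below 0.5x; below 0.2x.
    """
    return {
        "within_half_to_double": prob_relative_size(model, RelativeSizeQuery(0.5, 2.0)),
        "at_least_double": clade_size_survival(model, math.ceil(2 * model.mean)),
        "at_least_triple": clade_size_survival(model, math.ceil(3 * model.mean)),
        "below_half": 1.0 - clade_size_survival(model, math.ceil(0.5 * model.mean)),
        "below_fifth": 1.0 - clade_size_survival(model, math.ceil(0.2 * model.mean)),
    }
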