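"""Mutational effects on the cancer-defence level.

Effect sizes ``delta`` follow a generalized extreme value distribution with
shape -0.75, scale 1 and location -1 (MATLAB/Coles sign convention; under it
the support is unbounded below and capped at location + scale/0.75 = +1/3).
Draws below -1 are clamped to exactly -1, keeping every effect inside
[-1, +1]; delta = -1 wipes defences out entirely under the application rule.
The resulting distribution is strongly decay-biased: most mutations degrade
defences and large improvements are rare.

An effect modifies the defence level multiplicatively toward the nearer
boundary:

* ``delta > 0``:  d' = d + delta * (1 - d)   (toward full defence at 1)
* ``delta < 0``:  d' = d * (1 + delta)       (toward no defence at 0)

For the substitution engine the continuous distribution is discretized into
equal-probability categories at percentile midpoints (0.05, 0.15, ...,
99.95 for 1000 categories), each carrying mutation rate m/1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import genextreme

__all__ = [
    "MutationEffectDistribution",
    "MutationCategory",
    "sample_effect",
    "effect_quantile",
    "discretize",
    "apply_effect",
]


@dataclass(frozen=True)
class MutationEffectDistribution:
    """Truncated GEV law of defence-effect sizes.

    ``shape`` uses the MATLAB/Coles sign convention (scipy's ``genextreme``
    shape is its negative).  ``truncation="clamp"`` maps out-of-range draws
    onto the nearest clamp (an atom at -1); ``"reject"`` resamples them.
    """

    shape: float = -0.75
    scale: float = 1.0
    location: float = -1.0
    lower_clamp: float = -1.0
    upper_clamp: float = 1.0
    truncation: str = "clamp"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.lower_clamp >= self.upper_clamp:
            raise ValueError("lower_clamp must be below upper_clamp")
        if self.truncation not in ("clamp", "reject"):
            raise ValueError("truncation must be 'clamp' or 'reject'")

    @property
    def frozen(self):
        """The untruncated scipy distribution object."""
        return genextreme(c=-self.shape, loc=self.location, scale=self.scale)


@dataclass(frozen=True)
class MutationCategory:
    """One discretized effect class of the mutation distribution."""

    effect: float
    rate: float
    percentile: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("category rate must be non-negative")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")


def sample_effect(
    dist: MutationEffectDistribution, rng: np.random.Generator, size=None
):
    """Draw effect size(s) delta from the truncated distribution."""
    draws = dist.frozen.rvs(size=size if size is not None else 1, random_state=rng)
    if dist.truncation == "clamp":
        draws = np.clip(draws, dist.lower_clamp, dist.upper_clamp)
    else:
        bad = (draws < dist.lower_clamp) | (draws > dist.upper_clamp)
        while np.any(bad):
            draws[bad] = dist.frozen.rvs(size=int(bad.sum()), random_state=rng)
            bad = (draws < dist.lower_clamp) | (draws > dist.upper_clamp)
    return float(draws[0]) if size is None else draws


def effect_quantile(dist: MutationEffectDistribution, p):
    """Quantile of the truncated effect distribution at probability ``p``.

    Under clamping, all probability mass of the parent law below the lower
    clamp collapses onto an atom there, so small ``p`` return the clamp
    exactly.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("quantile probability must lie strictly inside (0, 1)")
    if dist.truncation == "clamp":
        q = dist.frozen.ppf(arr)
    else:
        lo, hi = dist.frozen.cdf([dist.lower_clamp, dist.upper_clamp])
        q = dist.frozen.ppf(lo + arr * (hi - lo))
    out = np.clip(q, dist.lower_clamp, dist.upper_clamp)
    return float(out) if np.isscalar(p) else out


def discretize(
    dist: MutationEffectDistribution,
    n_categories: int = 1000,
    total_rate: float = 1.0,
) -> list[MutationCategory]:
    """Equal-probability categories at percentile midpoints.

    With 1000 categories the effects sit at the 0.05th, 0.15th, ..., 99.95th
    percentiles, each occurring at rate ``total_rate / n_categories``.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if total_rate < 0:
        raise ValueError("total_rate must be non-negative")
    probs = (np.arange(n_categories) + 0.5) / n_categories
    effects = effect_quantile(dist, probs)
    rate = total_rate / n_categories
    return [
        MutationCategory(effect=float(e), rate=rate, percentile=float(100 * p))
        for e, p in zip(effects, probs)
    ]


def apply_effect(d, delta):
    """New defence level after an effect delta hits the level d.

    Positive effects move d toward 1 proportionally to the remaining headroom;
    negative effects shrink d proportionally (delta = -1 yields d' = 0).
    """
    d_arr = np.asarray(d, dtype=float)
    delta_arr = np.asarray(delta, dtype=float)
    if np.any((d_arr < 0) | (d_arr > 1)):
        raise ValueError("defence level must lie in [0, 1]")
    if np.any((delta_arr < -1) | (delta_arr > 1)):
        raise ValueError("effect size must lie in [-1, 1]")
    out = np.where(
        delta_arr >= 0,
        d_arr + delta_arr * (1.0 - d_arr),
        d_arr * (1.0 + delta_arr),
    )
    out = np.clip(out, 0.0, 1.0)
    return float(out) if (np.isscalar(d) and np.isscalar(delta)) else out
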