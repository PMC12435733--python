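"""Allometric maps from body mass to life-history quantities.

Body mass M (kg) determines, through published allometric relationships:

* the number of cells at risk of oncogenic mutation, ``N = M/70 * 3.72e13``
  (linear scaling anchored at the human estimate of 3.72e13 cells for 70 kg);
* the extrinsic (ecological) mortality rate, ``mu = e^-1.8 * M^-0.21`` per
  year, optionally multiplied by a reduction coefficient ``r < 1`` once the
  lineage has evolved flight;
* the effective population size, ``Ne = 10^(4 - 0.49*(log10 M + 3) + 1.96)``,
  where the ``+3`` converts kilograms to grams as in the underlying
  density-mass regression and the 10^4 factor corresponds to the assumed
  species range area;
* optionally, a mass-dependent rate of oncogenic steps ``k = kappa * M^-0.3``
  emulating the allometry of mass-specific metabolic rate, normalised so that
  ``k`` equals the constant-``k`` baseline at the mass where miniaturisation
  begins.

A :class:`BodySizeTrajectory` holds the exogenous body-size history
(piecewise-linear in time, years before present) and is the only
time-dependent input of the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllometryConstants",
    "BodySizeTrajectory",
    "Environment",
    "DEFAULT_CONSTANTS",
    "cell_count",
    "extrinsic_mortality_rate",
    "effective_population_size",
    "oncogenesis_rate",
    "mass_at_time",
    "make_environment",
]

SCENARIOS = ("miniaturisation", "constant_large", "constant_small")


@dataclass(frozen=True)
class AllometryConstants:
    """Coefficients of the allometric maps (defaults are the published values)."""

    cells_per_ref_mass: float = 3.72e13
    ref_mass: float = 70.0  # kg, human reference
    mort_coeff: float = math.exp(-1.8)  # per year at 1 kg
    mort_exponent: float = -0.21
    ne_area_coeff: float = 1e4  # species-range scale factor of Ne
    ne_exponent: float = -0.49
    ne_intercept: float = 1.96
    onco_exponent: float = -0.3

    def __post_init__(self) -> None:
        for name in (
            "cells_per_ref_mass",
            "ref_mass",
            "mort_coeff",
            "ne_area_coeff",
        ):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and positive, got {value!r}")


DEFAULT_CONSTANTS = AllometryConstants()


def _check_mass(mass: float) -> float:
    mass = float(mass)
    if not (np.isfinite(mass) and mass > 0):
        raise ValueError(f"body mass must be finite and positive, got {mass!r}")
    return mass


def cell_count(mass: float, constants: AllometryConstants = DEFAULT_CONSTANTS) -> float:
    """Number of cells of a body of ``mass`` kg (linear in mass)."""
    mass = _check_mass(mass)
    return mass / constants.ref_mass * constants.cells_per_ref_mass


def extrinsic_mortality_rate(
    mass: float,
    flighted: bool = False,
    r: float = 1.0,
    constants: AllometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Extrinsic mortality rate (per year); multiplied by ``r`` iff flighted."""
    mass = _check_mass(mass)
    if not (0.0 < r <= 1.0):
        raise ValueError(f"mortality reduction coefficient r must be in (0, 1], got {r!r}")
    rate = constants.mort_coeff * mass**constants.mort_exponent
    if flighted:
        rate *= r
    return rate


def effective_population_size(
    mass: float, constants: AllometryConstants = DEFAULT_CONSTANTS
) -> float:
    """Effective population size from the density-mass allometry.

    Kept continuous (not rounded): Ne only ever enters smooth expressions and
    rounding would introduce artificial steps along the mass trajectory.
    """
    mass = _check_mass(mass)
    log10_grams = math.log10(mass) + 3.0
    return constants.ne_area_coeff * 10.0 ** (
        constants.ne_exponent * log10_grams + constants.ne_intercept
    )


def oncogenesis_rate(
    mass: float,
    baseline_k: float,
    scaling_enabled: bool = False,
    ref_mass_start: float | None = None,
    constants: AllometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Rate of oncogenic steps k (per year).

    With ``scaling_enabled`` the rate follows ``kappa * M^-0.3`` with
    ``kappa = baseline_k * ref_mass_start^0.3`` so that the rate equals
    ``baseline_k`` at the start-of-miniaturisation mass; otherwise it is the
    constant ``baseline_k`` regardless of mass.
    """
    mass = _check_mass(mass)
    if baseline_k <= 0:
        raise ValueError(f"baseline oncogenesis rate must be positive, got {baseline_k!r}")
    if not scaling_enabled:
        return float(baseline_k)
    if ref_mass_start is None:
        raise ValueError("metabolic scaling requires the start-of-miniaturisation mass")
    ref_mass_start = _check_mass(ref_mass_start)
    kappa = baseline_k * ref_mass_start ** (-constants.onco_exponent)
    return kappa * mass**constants.onco_exponent


@dataclass(frozen=True)
class BodySizeTrajectory:
    """Piecewise-linear body-size history over macroevolutionary time.

    ``nodes`` are (time in years before present, mass in kg) pairs with times
    strictly decreasing; the mass is held constant at the youngest node's
    value from that node to the present.
    """

    nodes: tuple[tuple[float, float], ...]
    scenario_label: str = "miniaturisation"

    def __post_init__(self) -> None:
        nodes = tuple((float(t), float(m)) for t, m in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if not nodes:
            raise ValueError("trajectory needs at least one node")
        times = [t for t, _ in nodes]
        if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("node times must be strictly decreasing (oldest first)")
        if any(m <= 0 for _, m in nodes):
            raise ValueError("all node masses must be positive")
        if self.scenario_label not in SCENARIOS:
            raise ValueError(
                f"scenario_label must be one of {SCENARIOS}, got {self.scenario_label!r}"
            )

    @property
    def start_time(self) -> float:
        return self.nodes[0][0]

    @property
    def start_mass(self) -> float:
        return self.nodes[0][1]

    def mass_at(self, time):
        return mass_at_time(self, time)


def mass_at_time(trajectory: BodySizeTrajectory, time):
    """Body mass at ``time`` years before present (piecewise-linear).

    Times younger than the last node take the terminal mass; times outside
    ``[0, start_time]`` raise.
    """
    t = np.asarray(time, dtype=float)
    if np.any(t < 0) or np.any(t > trajectory.start_time):
        raise ValueError(
            f"time must be within [0, {trajectory.start_time:g}] years before present"
        )
    # np.interp expects increasing x: reverse the (decreasing-time) node order.
    times = np.array([n[0] for n in trajectory.nodes])[::-1]
    masses = np.array([n[1] for n in trajectory.nodes])[::-1]
    out = np.interp(t, times, masses)  # constant extrapolation at the young end
    return float(out) if np.isscalar(time) else out


@dataclass(frozen=True)
class Environment:
    """Mass-derived quantities at one macroevolutionary instant."""

    mass: float
    n_cells: float
    extrinsic_mortality: float
    ne: float
    onco_rate: float
    flighted: bool = False
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("environment needs at least one cell")
        for name in ("extrinsic_mortality", "ne", "onco_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def key(self) -> tuple:
        """Hashable identity of the physical state (for caching)."""
        return (self.mass, self.extrinsic_mortality, self.ne, self.onco_rate)


def make_environment(
    mass: float,
    baseline_k: float,
    flighted: bool = False,
    r: float = 1.0,
    metabolic_scaling: bool = False,
    ref_mass_start: float | None = None,
    constants: AllometryConstants = DEFAULT_CONSTANTS,
) -> Environment:
    """Build the full environment for a body mass and flight state."""
    return Environment(
        mass=_check_mass(mass),
        n_cells=cell_count(mass, constants),
        extrinsic_mortality=extrinsic_mortality_rate(mass, flighted, r, constants),
        ne=effective_population_size(mass, constants),
        onco_rate=oncogenesis_rate(
            mass, baseline_k, metabolic_scaling, ref_mass_start, constants
        ),
        flighted=bool(flighted),
        r=float(r),
    )
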