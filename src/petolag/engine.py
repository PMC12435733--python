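"""Origin-fixation substitution engine over macroevolutionary time.

Evolution of the cancer-defence level ``d`` is modelled as a sequence of
mutation-then-fixation events (no standing variation).  Each of the 1000
discretized mutation categories ``i`` has a per-generation fixation rate

    R_i = 4 Ne s_i m_i / (1 - exp(-4 Ne s_i)),

Kimura's origin-fixation rate with selection coefficient ``s_i`` of the
category's defence change and per-category mutation rate ``m_i = m/1000``.
Candidate fixations compete as independent exponential clocks (a Gillespie
race); the winner's waiting time in generations is converted to years with
the current expected lifespan L(d) as the generation-time proxy.

Macroevolutionary time (240 My by default) is divided into bins (4000 x
60000 y) within which the environment — body mass and everything derived
from it — is frozen.  A candidate fixation whose waiting time would cross
the current bin boundary is discarded; time jumps to the next bin start and
the environment (mass, mu, Ne, k, and hence L and W at the unchanged d) is
refreshed from the body-size trajectory, applying the flight mortality
reduction from the first bin whose start time has passed the flight date.
Runs start with no evolutionary lag: d is initialised at the optimum for the
starting environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .allometry import (
    SCENARIOS,
    AllometryConstants,
    BodySizeTrajectory,
    Environment,
    make_environment,
    mass_at_time,
)
from .lifehistory import LifespanTable, optimal_defence
from .mutation import MutationEffectDistribution, discretize

try:
    from . import _fastloop
except ImportError:  # pragma: no cover - numba is a declared dependency
    _fastloop = None

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "FixationEvent",
    "RunResult",
    "fixation_rate",
    "candidate_rates",
    "gillespie_draw",
    "run",
    "default_trajectory",
    "scenario_trajectory",
]

#: trajectory anchors printed for the miniaturising bird-stem lineage:
#: 220.7 kg at 240 Mya, ~163 kg at 198 Mya, 0.8 kg at 163 Mya, constant since.
MINIATURISATION_NODES = ((240e6, 220.7), (198e6, 163.0), (163e6, 0.8))


def default_trajectory() -> BodySizeTrajectory:
    """The three-anchor miniaturisation trajectory."""
    return BodySizeTrajectory(MINIATURISATION_NODES, "miniaturisation")


def scenario_trajectory(scenario: str) -> BodySizeTrajectory:
    """Body-size trajectory of a named scenario."""
    if scenario == "miniaturisation":
        return default_trajectory()
    if scenario == "constant_large":
        return BodySizeTrajectory(((240e6, 220.7),), "constant_large")
    if scenario == "constant_small":
        return BodySizeTrajectory(((240e6, 0.8),), "constant_small")
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass
class SimulationConfig:
    """Complete description of one simulation run."""

    scenario: str
    mutation_rate: float  # m, per genome per generation
    log10_cost: float
    n_steps: int = 3
    baseline_k: float = 1e-4
    metabolic_scaling: bool = False
    flighted: bool = False
    flight_time: float = 170e6  # years before present
    r: float = 1.0 / 3.0
    n_bins: int = 4000
    bin_width: float = 60000.0
    ne_area_coeff: float = 1e4
    seed: int = 0
    n_categories: int = 1000
    gev_shape: float = -0.75
    gev_scale: float = 1.0
    gev_location: float = -1.0
    gev_truncation: str = "clamp"
    gillespie_mode: str = "sum"  # "sum" or "literal" (statistically identical)
    trajectory: Optional[BodySizeTrajectory] = None
    #: explicit effect-size list replacing the discretized GEV categories
    #: (pluggable-distribution hook; each category still carries rate m/n)
    custom_effects: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate m must be non-negative")
        if self.flighted and self.scenario != "miniaturisation":
            raise ValueError("flight is only meaningful in the miniaturisation scenario")
        if not 0.0 < self.r <= 1.0:
            raise ValueError("mortality reduction r must lie in (0, 1]")
        if self.n_bins < 1 or self.bin_width <= 0:
            raise ValueError("need n_bins >= 1 and positive bin_width")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if self.gillespie_mode not in ("sum", "literal"):
            raise ValueError("gillespie_mode must be 'sum' or 'literal'")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.baseline_k <= 0:
            raise ValueError("baseline_k must be positive")
        if self.custom_effects is not None:
            eff = np.asarray(self.custom_effects, dtype=float)
            if eff.size < 1 or np.any((eff < -1) | (eff > 1)):
                raise ValueError("custom effects must be a non-empty list within [-1, 1]")

    @property
    def cost(self) -> float:
        return 10.0**self.log10_cost

    @property
    def span(self) -> float:
        """Total simulated span in years."""
        return self.n_bins * self.bin_width

    @property
    def constants(self) -> AllometryConstants:
        return AllometryConstants(ne_area_coeff=self.ne_area_coeff)

    def get_trajectory(self) -> BodySizeTrajectory:
        traj = self.trajectory or scenario_trajectory(self.scenario)
        if self.span > traj.start_time:
            raise ValueError(
                f"simulated span {self.span:g} y exceeds trajectory start "
                f"{traj.start_time:g} y"
            )
        return traj

    def mutation_distribution(self) -> MutationEffectDistribution:
        return MutationEffectDistribution(
            shape=self.gev_shape,
            scale=self.gev_scale,
            location=self.gev_location,
            truncation=self.gev_truncation,
        )

    def environment_at(self, time: float, trajectory: BodySizeTrajectory) -> Environment:
        """Environment at a macroevolutionary instant (flight by time rule)."""
        mass = mass_at_time(trajectory, time)
        flighted_now = self.flighted and time <= self.flight_time
        return make_environment(
            mass,
            baseline_k=self.baseline_k,
            flighted=flighted_now,
            r=self.r,
            metabolic_scaling=self.metabolic_scaling,
            ref_mass_start=trajectory.start_mass,
            constants=self.constants,
        )


@dataclass
class SimulationState:
    """Current point of the substitution process."""

    time: float  # years before present
    defence: float
    environment: Environment
    lifespan: float
    fitness: float


@dataclass(frozen=True)
class FixationEvent:
    """One substitution in the cancer-defence level."""

    time: float
    delta: float
    d_before: float
    d_after: float
    selection_coefficient: float
    tau_generations: float


def fixation_rate(s, ne, m_cat):
    """Kimura origin-fixation rate R = 4 Ne s m / (1 - exp(-4 Ne s)).

    Per-generation substitution rate of a mutation class with selection
    coefficient ``s``, mutation rate ``m_cat`` and effective population size
    ``ne``.  The neutral limit is ``m_cat`` (series expansion below
    |4 Ne s| = 1e-8); strongly deleterious classes are exponentially
    suppressed toward 0.
    """
    s_arr = np.asarray(s, dtype=float)
    x = 4.0 * ne * s_arr
    with np.errstate(over="ignore", invalid="ignore"):
        ratio = np.where(np.abs(x) < 1e-8, 1.0 + 0.5 * x, x / (-np.expm1(-x)))
    ratio = np.where(np.isfinite(ratio), ratio, 0.0)  # overflow: hopeless mutants
    out = np.asarray(m_cat, dtype=float) * ratio
    return float(out) if np.isscalar(s) else out


def candidate_rates(
    d: float,
    effects: np.ndarray,
    env: Environment,
    n_steps: int,
    cost: float,
    m_cat: float,
    table: LifespanTable,
):
    """Fixation rates of all mutation categories at resident defence ``d``.

    Returns ``(rates, d_primes, s)``.  Fitness is evaluated through the
    environment's lifespan table.
    """
    w_res = float(table.fitness(d, cost))
    if w_res <= 0.0:
        raise ValueError("resident fitness is zero; selection coefficients undefined")
    # inline apply_effect (argument checks already hold in the engine loop)
    d_primes = np.where(effects >= 0.0, d + effects * (1.0 - d), d * (1.0 + effects))
    s = table.fitness_batch(d_primes, cost) / w_res - 1.0
    rates = fixation_rate(s, env.ne, m_cat)
    return rates, d_primes, s


def gillespie_draw(rates: np.ndarray, rng: np.random.Generator, mode: str = "sum"):
    """Race of independent exponential fixation clocks.

    Returns ``(winner_index, tau_first)`` in generations, or ``(None, inf)``
    when no category has a positive rate.  ``mode="sum"`` draws the winning
    time from Exponential(sum R) and the winner proportionally to its rate —
    equal in law to ``mode="literal"``, which draws all clocks and takes the
    minimum.
    """
    total = float(rates.sum())
    if not total > 0.0:
        return None, math.inf
    if mode == "sum":
        tau = rng.exponential() / total
        u = rng.random() * total
        winner = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        winner = min(winner, len(rates) - 1)
        return winner, tau
    if mode == "literal":
        with np.errstate(divide="ignore"):
            scales = np.where(rates > 0.0, 1.0 / np.maximum(rates, 1e-300), np.inf)
        taus = np.where(rates > 0.0, rng.exponential(size=len(rates)) * scales, np.inf)
        winner = int(np.argmin(taus))
        return winner, float(taus[winner])
    raise ValueError(f"unknown gillespie mode {mode!r}")


class _RateKernel:
    """Exact candidate-rate evaluator specialised for one (environment, cost).

    Computes the same quantities as :func:`candidate_rates` — W(d') through
    the environment's lifespan spline and the Kimura rate per category — but
    exploits the category structure to cut redundant transcendental calls:

    * every clamp-atom category (delta = -1) maps to d' = 0, sharing a single
      precomputed fitness;
    * positive categories factor log10(1 - d') = log10(1-d) + log10(1-delta);
    * negative categories factor log(d') = log(d) + log1p(delta).

    The spline is evaluated on its own (uniform) knot grid directly.
    """

    def __init__(
        self,
        table: LifespanTable,
        cost: float,
        ne: float,
        m_cat: float,
        effects: np.ndarray,
    ) -> None:
        self.cost = cost
        self.m_cat = m_cat
        self.effects = effects
        spline = table._spline
        self._knots_x0 = float(spline.x[0])
        self._knots_dx = float(spline.x[1] - spline.x[0])
        self._coeffs = spline.c  # (4, n_knots-1)
        self._n_int = spline.c.shape[1]
        self._x_min = table.X_MIN
        self.pos = np.flatnonzero(effects > 0.0)
        self.atom = np.flatnonzero(effects <= -1.0)
        self.neg = np.flatnonzero((effects < 0.0) & (effects > -1.0))
        self.zero = np.flatnonzero(effects == 0.0)
        self._delta_pos = effects[self.pos]
        self._log10_1m_delta_pos = np.log10(1.0 - self._delta_pos)
        self.ne = ne
        self._delta_neg = effects[self.neg]
        self._log1p_delta_neg = np.log1p(self._delta_neg)
        self._w_at_zero = float(self._spline_eval(np.array([0.0]))[0])  # W(0)=L(0)

    def resident(self, d: float) -> tuple[float, float]:
        """(lifespan, fitness) of the resident defence level."""
        if d >= 1.0:
            raise ValueError("resident defence must be below 1")
        L = float(self._spline_eval(np.array([math.log10(1.0 - d)]))[0])
        f = 1.0 if d == 0.0 else -math.expm1(math.log(d) / self.cost)
        return L, L * f

    def _spline_eval(self, x: np.ndarray) -> np.ndarray:
        np.maximum(x, self._x_min, out=x)
        pos = (x - self._knots_x0) / self._knots_dx
        idx = np.minimum(pos.astype(np.intp), self._n_int - 1)
        t = x - (self._knots_x0 + idx * self._knots_dx)
        c = self._coeffs
        return ((c[0, idx] * t + c[1, idx]) * t + c[2, idx]) * t + c[3, idx]

    def rates(self, d: float, w_res: float):
        """(rates, d_primes, s) for all categories at resident defence d."""
        n = len(self.effects)
        d_primes = np.empty(n)
        w = np.empty(n)
        log10_1m_d = math.log10(1.0 - d)
        log_d = math.log(d) if d > 0.0 else -math.inf

        dp = d + self._delta_pos * (1.0 - d)
        d_primes[self.pos] = dp
        x = log10_1m_d + self._log10_1m_delta_pos
        w[self.pos] = self._spline_eval(x) * -np.expm1(np.log(dp) / self.cost)

        dn = d * (1.0 + self._delta_neg)
        d_primes[self.neg] = dn
        ln_dn = log_d + self._log1p_delta_neg
        x = np.log10(1.0 - dn)
        w[self.neg] = self._spline_eval(x) * -np.expm1(ln_dn / self.cost)

        d_primes[self.atom] = 0.0
        w[self.atom] = self._w_at_zero

        if len(self.zero):
            d_primes[self.zero] = d
            w[self.zero] = w_res

        s = w / w_res - 1.0
        return fixation_rate(s, self.ne, self.m_cat), d_primes, s


@dataclass
class RunResult:
    """Per-bin snapshots, the fixation log and end-of-run state."""

    config: SimulationConfig
    snapshots: pd.DataFrame
    events: pd.DataFrame
    final_state: SimulationState
    d_initial: float

    @property
    def n_fixations(self) -> int:
        return len(self.events)


_SNAPSHOT_COLS = (
    "time_mya",
    "defence",
    "mass_kg",
    "lifespan_y",
    "fitness",
    "ne",
    "mu",
    "k",
)
_EVENT_COLS = (
    "time_mya",
    "delta",
    "d_before",
    "d_after",
    "s",
    "tau_generations",
)


def _spline_arrays(table: LifespanTable):
    """Unpack the lifespan spline into plain arrays for the compiled loop."""
    spline = table._spline
    x = spline.x
    c = np.ascontiguousarray(spline.c)
    return (
        float(x[0]),
        float(x[1] - x[0]),
        c[0].copy(),
        c[1].copy(),
        c[2].copy(),
        c[3].copy(),
    )


def _get_table(env: Environment, n_steps: int, cache: dict | None) -> LifespanTable:
    if cache is None:
        return LifespanTable(env, n_steps)
    key = (env.key(), n_steps)
    table = cache.get(key)
    if table is None:
        table = cache[key] = LifespanTable(env, n_steps)
    return table


def run(config: SimulationConfig, table_cache: dict | None = None) -> RunResult:
    """Simulate the full span and return snapshots plus the fixation log.

    ``table_cache`` optionally shares lifespan tables across runs: the
    environment sequence depends only on the scenario (not on cost or
    mutation rate), so parameter sweeps reuse the same tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trajectory = config.get_trajectory()
    cost = config.cost
    if config.custom_effects is not None:
        effects = np.sort(np.asarray(config.custom_effects, dtype=float))
    else:
        effects = np.array(
            [
                c.effect
                for c in discretize(
                    config.mutation_distribution(),
                    config.n_categories,
                    config.mutation_rate,
                )
            ]
        )
    m_cat = config.mutation_rate / len(effects)

    span = config.span
    env = config.environment_at(span, trajectory)
    table = _get_table(env, config.n_steps, table_cache)
    d, _, _ = optimal_defence(env, config.n_steps, cost, table)
    d_initial = d

    snapshots: list[tuple] = []
    events: list[tuple] = []
    event_frames: list[pd.DataFrame] = []
    T = span
    kernel = _RateKernel(table, cost, env.ne, m_cat, effects)
    rates = None  # cached for (env, d); invalidated on change of either

    use_fast = (
        config.gillespie_mode == "sum"
        and config.mutation_rate > 0.0
        and _fastloop is not None
    )
    if use_fast:
        _fastloop.seed_rng(config.seed % 2**32)
        n_atom = int(np.searchsorted(effects, -1.0, side="right"))
        spline_args = _spline_arrays(table)
        with np.errstate(divide="ignore", invalid="ignore"):
            pre_log10 = np.where(effects >= 0.0, np.log10(1.0 - effects), 0.0)
            pre_log1p = np.where(effects < 0.0, np.log1p(effects), 0.0)

    for i in range(config.n_bins):
        bin_start = span - i * config.bin_width
        bin_end = span - (i + 1) * config.bin_width
        if i > 0:
            new_env = config.environment_at(bin_start, trajectory)
            if new_env.key() != env.key():
                env = new_env
                table = _get_table(env, config.n_steps, table_cache)
                kernel = _RateKernel(table, cost, env.ne, m_cat, effects)
                rates = None
                if use_fast:
                    spline_args = _spline_arrays(table)
        L, W = kernel.resident(d)
        snapshots.append(
            (
                bin_start / 1e6,
                d,
                env.mass,
                L,
                W,
                env.ne,
                env.extrinsic_mortality,
                env.onco_rate,
            )
        )
        if use_fast:
            if W <= 0.0:
                raise ValueError("resident fitness is zero; selection undefined")
            d, T, ev_t, ev_delta, ev_db, ev_da, ev_s, ev_tau = _fastloop.run_bin(
                d, T, bin_end, effects, pre_log10, pre_log1p, n_atom, cost,
                4.0 * env.ne, m_cat, *spline_args,
            )
            if len(ev_t):
                event_frames.append(
                    pd.DataFrame(
                        {
                            "time_mya": ev_t / 1e6,
                            "delta": ev_delta,
                            "d_before": ev_db,
                            "d_after": ev_da,
                            "s": ev_s,
                            "tau_generations": ev_tau,
                        }
                    )
                )
            continue
        while True:
            if rates is None:
                if config.mutation_rate == 0.0:
                    rates = np.zeros_like(effects)
                    d_primes = s_arr = rates
                else:
                    if W <= 0.0:
                        raise ValueError(
                            "resident fitness is zero; selection undefined"
                        )
                    rates, d_primes, s_arr = kernel.rates(d, W)
            winner, tau = gillespie_draw(rates, rng, config.gillespie_mode)
            if winner is None:
                T = bin_end
                break
            dT = tau * L
            if T - dT > bin_end:  # fixation lands inside the current bin
                T = T - dT
                d_new = float(d_primes[winner])
                events.append(
                    (
                        T / 1e6,
                        float(effects[winner]),
                        d,
                        d_new,
                        float(s_arr[winner]),
                        tau,
                    )
                )
                d = d_new
                L, W = kernel.resident(d)
                rates = None
            else:  # would cross the boundary: discard, advance to next bin
                T = bin_end
                break

    L, W = kernel.resident(d)
    snapshots.append(
        (0.0, d, env.mass, L, W, env.ne, env.extrinsic_mortality, env.onco_rate)
    )
    final_state = SimulationState(
        time=0.0, defence=d, environment=env, lifespan=L, fitness=W
    )
    if event_frames:
        events_df = pd.concat(event_frames, ignore_index=True)[list(_EVENT_COLS)]
    else:
        events_df = pd.DataFrame(events, columns=_EVENT_COLS)
    return RunResult(
        config=config,
        snapshots=pd.DataFrame(snapshots, columns=_SNAPSHOT_COLS),
        events=events_df,
        final_state=final_state,
        d_initial=d_initial,
    )
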