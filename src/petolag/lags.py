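"""Evolutionary-lag metrics and the cost x mutation-rate parameter sweep.

A lineage whose defences cannot track the moving optimum ends the simulation
mismatched to its final environment.  The mismatch is quantified against the
optimum of the end-of-run environment (d*, W_max = W(d*), L* = L(d*)):

* lag in defences   Delta_d = d_final - d*
* lag in lifespan   Delta_L = L_final / L(d*)
* lag in fitness    Delta_W = W_final / W(d*)   (always <= 1)

plus the probability that cancer ends life (pCEL) at the evolved defence
level.  The sweep explores a dense unreplicated grid of trade-off costs
(log10 c in [-4.1, -0.1]) and genome-wide mutation rates (log10 m in
[-15, 0]) across scenario variants, one run per cell with a per-cell seed
derived from the master seed.  The *mutational boundary* of a cost column is
the smallest mutation rate at which at least one substitution fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import Environment
from .engine import RunResult, SimulationConfig, run
from .lifehistory import (
    LifespanTable,
    optimal_defence,
    params_for,
    prob_cancer_death,
)

__all__ = [
    "LagMetrics",
    "SweepGrid",
    "SCENARIO_VARIANTS",
    "compute_lags",
    "lags_of_run",
    "run_sweep",
    "mutational_boundary",
]

#: Named scenario variants matching the model's flight x metabolic-scaling
#: design: the three body-size scenarios, with the miniaturising lineage in
#: all four combinations of flight and oncogenesis-rate scaling.
SCENARIO_VARIANTS: dict[str, dict] = {
    "constant_large": {"scenario": "constant_large"},
    "constant_small": {"scenario": "constant_small"},
    "mini_flightless_constant_k": {"scenario": "miniaturisation"},
    "mini_flighted_constant_k": {"scenario": "miniaturisation", "flighted": True},
    "mini_flightless_scaling_k": {
        "scenario": "miniaturisation",
        "metabolic_scaling": True,
    },
    "mini_flighted_scaling_k": {
        "scenario": "miniaturisation",
        "flighted": True,
        "metabolic_scaling": True,
    },
}


@dataclass(frozen=True)
class LagMetrics:
    """End-of-run mismatch relative to the current optimum."""

    delta_d: float
    delta_L: float
    delta_W: float
    p_cel_final: float
    d_star: float
    l_star: float
    w_max: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.delta_d <= 1.0:
            raise ValueError("defence lag must lie in [-1, 1]")


def compute_lags(
    d_final: float,
    env: Environment,
    n_steps: int,
    cost: float,
    table: LifespanTable | None = None,
) -> LagMetrics:
    """Lag metrics of a final defence level in its end-of-run environment."""
    if table is None:
        table = LifespanTable(env, n_steps)
    d_star, w_max, l_star = optimal_defence(env, n_steps, cost, table)
    if w_max <= 0.0:
        raise ValueError("degenerate environment: maximal fitness is zero")
    l_final = float(table(d_final))
    w_final = float(table.fitness(d_final, cost))
    if d_final >= 1.0:
        p_cel = 0.0
    else:
        p_cel = prob_cancer_death(params_for(env, n_steps, cost, d_final))
    return LagMetrics(
        delta_d=d_final - d_star,
        delta_L=l_final / l_star,
        delta_W=w_final / w_max,
        p_cel_final=p_cel,
        d_star=d_star,
        l_star=l_star,
        w_max=w_max,
    )


def lags_of_run(result: RunResult, table: LifespanTable | None = None) -> LagMetrics:
    """Lag metrics at the end of a completed simulation run."""
    return compute_lags(
        result.final_state.defence,
        result.final_state.environment,
        result.config.n_steps,
        result.config.cost,
        table=table,
    )


@dataclass
class SweepGrid:
    """Gradient design over trade-off cost and mutation rate."""

    log10_cost_values: np.ndarray = field(
        default_factory=lambda: np.linspace(-4.1, -0.1, 41)
    )
    log10_m_values: np.ndarray = field(
        default_factory=lambda: np.linspace(-15.0, 0.0, 31)
    )
    variants: tuple[str, ...] = ("mini_flightless_constant_k",)
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.log10_cost_values = np.asarray(self.log10_cost_values, dtype=float)
        self.log10_m_values = np.asarray(self.log10_m_values, dtype=float)
        unknown = set(self.variants) - set(SCENARIO_VARIANTS)
        if unknown:
            raise ValueError(f"unknown scenario variants: {sorted(unknown)}")


def _cell_seed(master_seed: int, variant_idx: int, ci: int, mi: int) -> int:
    """Stable per-cell seed: adding cells never perturbs existing ones."""
    ss = np.random.SeedSequence((master_seed, variant_idx, ci, mi))
    return int(ss.generate_state(1)[0] % 2**31)


_SWEEP_COLS = (
    "scenario",
    "log10_c",
    "log10_m",
    "seed",
    "n_fixations",
    "d_final",
    "d_star",
    "delta_d",
    "delta_L",
    "delta_W",
    "p_cel",
)


def run_sweep(
    grid: SweepGrid,
    base_config: SimulationConfig | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """One run per (variant, cost, mutation-rate) cell, without replication.

    Per-cell failures are recorded (``error`` column) and the sweep
    continues.  Lifespan tables are shared across cells of a variant, since
    the environment sequence does not depend on cost or mutation rate.
    """
    rows = []
    for vi, variant in enumerate(grid.variants):
        overrides = SCENARIO_VARIANTS[variant]
        table_cache: dict = {}
        lag_tables: dict = {}
        for ci, log10_c in enumerate(grid.log10_cost_values):
            for mi, log10_m in enumerate(grid.log10_m_values):
                seed = _cell_seed(grid.master_seed, vi, ci, mi)
                row = {
                    "scenario": variant,
                    "log10_c": float(log10_c),
                    "log10_m": float(log10_m),
                    "seed": seed,
                    "error": "",
                }
                try:
                    cfg_kwargs = dict(
                        mutation_rate=10.0**log10_m,
                        log10_cost=float(log10_c),
                        seed=seed,
                        **overrides,
                    )
                    if base_config is not None:
                        for name in (
                            "n_steps",
                            "baseline_k",
                            "flight_time",
                            "r",
                            "n_bins",
                            "bin_width",
                            "ne_area_coeff",
                            "n_categories",
                        ):
                            cfg_kwargs.setdefault(name, getattr(base_config, name))
                    cfg = SimulationConfig(**cfg_kwargs)
                    result = run(cfg, table_cache=table_cache)
                    env = result.final_state.environment
                    key = (env.key(), cfg.n_steps)
                    table = table_cache.get(key)
                    lags = compute_lags(
                        result.final_state.defence,
                        env,
                        cfg.n_steps,
                        cfg.cost,
                        table=table,
                    )
                    row.update(
                        n_fixations=result.n_fixations,
                        d_final=result.final_state.defence,
                        d_star=lags.d_star,
                        delta_d=lags.delta_d,
                        delta_L=lags.delta_L,
                        delta_W=lags.delta_W,
                        p_cel=lags.p_cel_final,
                    )
                except Exception as exc:  # record and continue
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
                if progress:
                    print(
                        f"[{variant}] log10_c={log10_c:+.2f} "
                        f"log10_m={log10_m:+.2f} -> "
                        f"{row.get('n_fixations', 'ERR')} fixations"
                    )
    df = pd.DataFrame(rows)
    return df[[*_SWEEP_COLS, "error"]]


def mutational_boundary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Smallest log10 m with at least one fixation, per (variant, cost) column.

    Columns with no fixations anywhere get NaN.
    """
    ok = sweep[sweep["error"] == ""] if "error" in sweep else sweep
    fixed = ok[ok["n_fixations"] >= 1]
    out = (
        fixed.groupby(["scenario", "log10_c"])["log10_m"]
        .min()
        .rename("boundary_log10_m")
        .reset_index()
    )
    all_cols = ok[["scenario", "log10_c"]].drop_duplicates()
    return all_cols.merge(out, on=["scenario", "log10_c"], how="left")
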