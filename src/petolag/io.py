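"""Configuration files, trajectory CSVs, result writers and run records.

* Config files are YAML with keys mirroring
  :class:`petolag.engine.SimulationConfig` fields; unknown keys are
  rejected.
* Trajectory CSVs have two columns ``time_mya,mass_kg`` (header required,
  rows oldest-first with strictly decreasing times).
* A completed run writes a trajectory CSV (per-bin snapshots), an events CSV
  (fixation log) and a JSON run record sufficient to reproduce it; a sweep
  writes a summary CSV plus the record.

Exit-code convention of the CLI: 0 success, 2 configuration error,
3 numeric failure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allometry import BodySizeTrajectory
from .engine import RunResult, SimulationConfig, default_trajectory

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "default_trajectory",
    "write_outputs",
    "write_sweep_outputs",
]

__version__ = "0.1.0"


class ConfigError(ValueError):
    """A run configuration file failed validation."""


_CONFIG_FIELDS = {
    f.name: f for f in dataclasses.fields(SimulationConfig) if f.name != "trajectory"
}


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML run configuration.

    ``trajectory_csv`` may name a CSV file (resolved relative to the config
    file) overriding the scenario's built-in body-size trajectory.
    ``log10_m`` is accepted as an alternative to ``mutation_rate``.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    if "log10_m" in raw:
        if "mutation_rate" in raw:
            raise ConfigError(f"{path}: give either mutation_rate or log10_m, not both")
        raw["mutation_rate"] = 10.0 ** float(raw.pop("log10_m"))
    trajectory = None
    if "trajectory_csv" in raw:
        csv_path = Path(raw.pop("trajectory_csv"))
        if not csv_path.is_absolute():
            csv_path = path.parent / csv_path
        trajectory = read_trajectory_csv(csv_path)
    unknown = set(raw) - set(_CONFIG_FIELDS)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "scenario" not in raw:
        raise ConfigError(f"{path}: required key 'scenario' is missing")
    if "mutation_rate" not in raw:
        raise ConfigError(f"{path}: required key 'mutation_rate' (or log10_m) is missing")
    if "log10_cost" not in raw:
        raise ConfigError(f"{path}: required key 'log10_cost' is missing")
    try:
        return SimulationConfig(trajectory=trajectory, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: SimulationConfig, path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    data = dataclasses.asdict(config)
    data.pop("trajectory")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_trajectory_csv(path, scenario_label: str = "miniaturisation") -> BodySizeTrajectory:
    """Read a ``time_mya,mass_kg`` CSV into a body-size trajectory."""
    df = pd.read_csv(path)
    expected = ["time_mya", "mass_kg"]
    if list(df.columns) != expected:
        raise ConfigError(f"{path}: trajectory CSV must have columns {expected}")
    times = df["time_mya"].to_numpy(dtype=float) * 1e6
    masses = df["mass_kg"].to_numpy(dtype=float)
    if np.any(np.diff(times) >= 0):
        raise ConfigError(f"{path}: node times must strictly decrease (oldest first)")
    return BodySizeTrajectory(tuple(zip(times, masses)), scenario_label)


def write_trajectory_csv(trajectory: BodySizeTrajectory, path) -> None:
    df = pd.DataFrame(
        {
            "time_mya": [t / 1e6 for t, _ in trajectory.nodes],
            "mass_kg": [m for _, m in trajectory.nodes],
        }
    )
    df.to_csv(path, index=False)


def _run_record(config: SimulationConfig, extra: dict) -> dict:
    data = dataclasses.asdict(config)
    traj = data.pop("trajectory")
    record = {
        "package": "petolag",
        "version": __version__,
        "config": data,
        "trajectory_nodes": None if traj is None else traj["nodes"],
    }
    record.update(extra)
    return record


def write_outputs(result: RunResult, out_dir) -> dict:
    """Write snapshots, events and the run record; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": out / "trajectory.csv",
        "events": out / "events.csv",
        "record": out / "run_record.json",
    }
    fmt = "%.17g"
    result.snapshots.to_csv(paths["trajectory"], index=False, float_format=fmt)
    result.events.to_csv(paths["events"], index=False, float_format=fmt)
    record = _run_record(
        result.config,
        {
            "d_initial": result.d_initial,
            "d_final": result.final_state.defence,
            "n_fixations": result.n_fixations,
            "files": {k: p.name for k, p in paths.items()},
        },
    )
    paths["record"].write_text(json.dumps(record, indent=2))
    return {k: str(p) for k, p in paths.items()}


def write_sweep_outputs(sweep: pd.DataFrame, grid, base_config, out_dir) -> dict:
    """Write the sweep summary CSV plus a record of the grid and master seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"sweep": out / "sweep.csv", "record": out / "sweep_record.json"}
    sweep.to_csv(paths["sweep"], index=False, float_format="%.17g")
    record = {
        "package": "petolag",
        "version": __version__,
        "master_seed": int(grid.master_seed),
        "log10_cost_values": [float(v) for v in grid.log10_cost_values],
        "log10_m_values": [float(v) for v in grid.log10_m_values],
        "variants": list(grid.variants),
        "files": {k: p.name for k, p in paths.items()},
    }
    if base_config is not None:
        record["base_config"] = _run_record(base_config, {})["config"]
    paths["record"].write_text(json.dumps(record, indent=2))
    return {k: str(p) for k, p in paths.items()}
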