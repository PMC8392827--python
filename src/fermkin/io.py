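"""Configuration and file I/O.

Formats
-------
* Run configuration: YAML with sections ``kinetics``, ``coupling``,
  ``initial_state``, ``protocol``, ``simulation``, ``noise``,
  ``pso_stage1``, ``pso_stage2`` and a top-level ``seed``.  Initial
  concentrations declare their unit (``mg/L`` or ``g/L``); mg/L values
  are converted to the internal g/L on load.
* Datasets: CSV with columns ``time_h, co2_gL, ref_temp_C`` (+ optional
  ``temp_C``); generating metadata, when present, in a ``.meta.json``
  sidecar next to the CSV.
* Trajectories: CSV with ``time_h, x1_gL, x2_gL, x3_gL`` (+ ``temp_C``,
  ``ref_temp_C`` for the 4-state model).
* Identification results: JSON (names, values, units, objective,
  iterations, seed, bounds) plus a convergence-history CSV
  (``iteration, best_iae``).

Times are always hours, temperatures degC, concentrations g/L in files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datasets import MeasuredDataset
from .exceptions import ConfigError, InvalidInputError
from .identify import IdentificationResult, PSOConfig
from .kinetics import FermentationState, KineticParameters, TemperatureCoupling
from .simulate import TemperatureProfile, Trajectory, constant_profile, make_step_profile

__all__ = [
    "RunConfig",
    "load_config",
    "read_dataset",
    "write_dataset",
    "write_trajectory",
    "read_trajectory",
    "write_result",
    "write_history",
]

_DATASET_COLUMNS = ["time_h", "co2_gL", "ref_temp_C"]


@dataclass
class RunConfig:
    """Validated contents of a run-configuration file."""

    kinetics: Optional[KineticParameters] = None
    coupling: Optional[TemperatureCoupling] = None
    init: Optional[FermentationState] = None
    profile: Optional[TemperatureProfile] = None
    t_end: float = 24.0
    dt_sample: float = 1.0 / 6.0
    rtol: float = 1e-8
    atol: float = 1e-10
    noise_sd: Optional[float] = 0.0
    filter_tau: float = 0.0
    pso_stage1: Optional[PSOConfig] = None
    pso_stage2: Optional[PSOConfig] = None
    seed: Optional[int] = None

    def require(self, *sections: str) -> None:
        """Raise a :class:`ConfigError` naming any missing section."""
        for s in sections:
            if getattr(self, s) is None:
                raise ConfigError(f"configuration section {s!r} is required for this command")


def _section(data: dict, key: str) -> Optional[dict]:
    v = data.get(key)
    if v is None:
        return None
    if not isinstance(v, dict):
        raise ConfigError(f"config section {key!r} must be a mapping")
    return v


def _get(sec: dict, secname: str, key: str, default=None, required=False):
    if key not in sec:
        if required:
            raise ConfigError(f"missing key {secname}.{key}")
        return default
    return sec[key]


def _parse_kinetics(sec: dict) -> KineticParameters:
    vals = {k: float(_get(sec, "kinetics", k, required=True)) for k in KineticParameters.NAMES}
    extra = set(sec) - set(KineticParameters.NAMES)
    if extra:
        raise ConfigError(f"unknown keys in kinetics: {sorted(extra)}")
    try:
        return KineticParameters(**vals)
    except InvalidInputError as err:
        raise ConfigError(f"kinetics: {err}") from err


def _parse_coupling(sec: dict) -> TemperatureCoupling:
    vals = {k: float(_get(sec, "coupling", k, required=True)) for k in TemperatureCoupling.NAMES}
    try:
        return TemperatureCoupling(**vals)
    except InvalidInputError as err:
        raise ConfigError(f"coupling: {err}") from err


def _parse_init(sec: dict) -> FermentationState:
    unit = _get(sec, "initial_state", "unit", required=True)
    if unit not in ("mg/L", "g/L"):
        raise ConfigError(f"initial_state.unit must be 'mg/L' or 'g/L', got {unit!r}")
    scale = 1e-3 if unit == "mg/L" else 1.0
    x = [float(_get(sec, "initial_state", k, required=True)) * scale for k in ("x1", "x2", "x3")]
    temp = _get(sec, "initial_state", "temp_C")
    try:
        return FermentationState(x[0], x[1], x[2], None if temp is None else float(temp))
    except InvalidInputError as err:
        raise ConfigError(f"initial_state: {err}") from err


def _parse_profile(sec: dict) -> TemperatureProfile:
    kind = _get(sec, "protocol", "kind", required=True)
    if kind == "constant":
        return constant_profile(float(_get(sec, "protocol", "temp_C", required=True)))
    if kind == "step":
        return make_step_profile(
            float(_get(sec, "protocol", "theta_start_C", required=True)),
            float(_get(sec, "protocol", "theta_end_C", required=True)),
            float(_get(sec, "protocol", "step_time_h", required=True)),
        )
    if kind == "breakpoints":
        bps = _get(sec, "protocol", "breakpoints", required=True)
        return TemperatureProfile(tuple((float(t), float(v)) for t, v in bps))
    raise ConfigError(f"protocol.kind must be constant|step|breakpoints, got {kind!r}")


def _parse_pso(sec: dict, secname: str) -> PSOConfig:
    known = {
        "swarm_size", "inertia_range", "self_weight", "social_weight",
        "max_iterations", "stall_iterations", "function_tolerance", "seed",
    }
    extra = set(sec) - known
    if extra:
        raise ConfigError(f"unknown keys in {secname}: {sorted(extra)}")
    kwargs = dict(sec)
    if "inertia_range" in kwargs:
        kwargs["inertia_range"] = tuple(float(v) for v in kwargs["inertia_range"])
    try:
        return PSOConfig(**kwargs)
    except InvalidInputError as err:
        raise ConfigError(f"{secname}: {err}") from err


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    if (sec := _section(data, "kinetics")) is not None:
        cfg.kinetics = _parse_kinetics(sec)
    if (sec := _section(data, "coupling")) is not None:
        cfg.coupling = _parse_coupling(sec)
    if (sec := _section(data, "initial_state")) is not None:
        cfg.init = _parse_init(sec)
    if (sec := _section(data, "protocol")) is not None:
        cfg.profile = _parse_profile(sec)
    if (sec := _section(data, "simulation")) is not None:
        cfg.t_end = float(_get(sec, "simulation", "t_end_h", cfg.t_end))
        cfg.dt_sample = float(_get(sec, "simulation", "dt_sample_h", cfg.dt_sample))
        cfg.rtol = float(_get(sec, "simulation", "rtol", cfg.rtol))
        cfg.atol = float(_get(sec, "simulation", "atol", cfg.atol))
        if cfg.t_end <= 0 or cfg.dt_sample <= 0:
            raise ConfigError("simulation.t_end_h and simulation.dt_sample_h must be > 0")
    if (sec := _section(data, "noise")) is not None:
        sd = _get(sec, "noise", "sd_gL", 0.0)
        cfg.noise_sd = None if sd == "auto" else float(sd)
        cfg.filter_tau = float(_get(sec, "noise", "filter_tau_h", 0.0))
    if (sec := _section(data, "pso_stage1")) is not None:
        cfg.pso_stage1 = _parse_pso(sec, "pso_stage1")
    if (sec := _section(data, "pso_stage2")) is not None:
        cfg.pso_stage2 = _parse_pso(sec, "pso_stage2")
    if "seed" in data and data["seed"] is not None:
        cfg.seed = int(data["seed"])
    return cfg


def _profile_from_reference(times: np.ndarray, ref: np.ndarray) -> TemperatureProfile:
    """Reconstruct a piecewise-constant protocol from a sampled u(t)."""
    bps = [(0.0, float(ref[0]))]
    for t, prev, cur in zip(times[1:], ref[:-1], ref[1:]):
        if cur != prev:
            bps.append((float(t), float(cur)))
    return TemperatureProfile(tuple(bps))


def write_dataset(dataset: MeasuredDataset, path) -> None:
    """Dataset to CSV (+ ``.meta.json`` sidecar when metadata is present)."""
    path = Path(path)
    dataset.to_dataframe().to_csv(path, index=False)
    if dataset.meta:
        meta = {k: v for k, v in dataset.meta.items() if k != "truth_x3"}
        with open(path.with_suffix(".meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def read_dataset(path) -> MeasuredDataset:
    """Dataset from CSV; round-trips :func:`write_dataset` to ~1e-15."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"dataset {path} is missing columns {missing}")
    extra = [c for c in df.columns if c not in _DATASET_COLUMNS + ["temp_C"]]
    if extra:
        raise InvalidInputError(f"dataset {path} has unexpected columns {extra}")
    times = df["time_h"].to_numpy(float)
    if times.size >= 2 and np.any(np.diff(times) <= 0):
        raise InvalidInputError(f"dataset {path}: time_h must be strictly increasing")
    profile = _profile_from_reference(times, df["ref_temp_C"].to_numpy(float))
    meta = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    temp = df["temp_C"].to_numpy(float) if "temp_C" in df.columns else None
    return MeasuredDataset(times=times, co2=df["co2_gL"].to_numpy(float),
                           profile=profile, measured_temp=temp, meta=meta)


def write_trajectory(trajectory: Trajectory, path) -> None:
    trajectory.to_dataframe().to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    for c in ("time_h", "x1_gL", "x2_gL", "x3_gL"):
        if c not in df.columns:
            raise InvalidInputError(f"trajectory {path} is missing column {c!r}")
    return Trajectory(
        times=df["time_h"].to_numpy(float),
        x1=df["x1_gL"].to_numpy(float),
        x2=df["x2_gL"].to_numpy(float),
        x3=df["x3_gL"].to_numpy(float),
        temp=df["temp_C"].to_numpy(float) if "temp_C" in df.columns else None,
        ref_temp=df["ref_temp_C"].to_numpy(float) if "ref_temp_C" in df.columns else None,
        model_tag="temperature_considered" if "temp_C" in df.columns else "fundamental",
    )


_UNITS = dict(zip(KineticParameters.NAMES, KineticParameters.UNITS))
_UNITS.update(zip(TemperatureCoupling.NAMES, TemperatureCoupling.UNITS))


def write_result(result: IdentificationResult, path) -> None:
    """Identification result to JSON (parameters, objective, diagnostics)."""
    names = result.parameter_names or [f"x{i}" for i in range(result.x.size)]
    payload = {
        "parameters": [
            {"name": n, "value": float(v), "unit": _UNITS.get(n, "")}
            for n, v in zip(names, result.x)
        ],
        "objective_iae_ghL": result.objective_value,
        "iterations": result.iterations,
        "n_evaluations": result.n_evaluations,
        "seed": result.seed,
        "bounds": [list(b) for b in (result.bounds or [])],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_history(result: IdentificationResult, path) -> None:
    """Best objective per iteration to CSV (``iteration, best_iae``)."""
    pd.DataFrame({
        "iteration": np.arange(len(result.history)),
        "best_iae": result.history,
    }).to_csv(path, index=False)
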