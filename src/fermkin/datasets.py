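"""Synthetic measured-experiment generation.

Emulates the laboratory measurement chain around the batch bioreactor:
~24 h fermentations, dissolved-CO2 sampled every 10 min by an ion-selective
electrode, optional additive Gaussian sensor noise passed through a
discrete first-order low-pass filter (the hardware applies an analog one
before acquisition).  The reference configuration below is the identified
laboratory operating point: initial loading (2.6, 9.0, 0.1) mg/L
harmonised to g/L, fermentation start at 22 degC, and the nine identified
model constants.

These generators are the input side of every identification and acceptance
experiment in the package; no external data files are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import InvalidInputError
from .kinetics import FermentationState, KineticParameters, TemperatureCoupling
from .simulate import (
    DEFAULT_ATOL,
    DEFAULT_DT_SAMPLE,
    DEFAULT_RTOL,
    DEFAULT_T_END,
    TemperatureProfile,
    constant_profile,
    make_step_profile,
    simulate,
)

__all__ = [
    "MeasuredDataset",
    "generate_experiment",
    "reference_constant_dataset",
    "reference_step_dataset",
    "REFERENCE_KINETICS",
    "REFERENCE_COUPLING",
    "REFERENCE_INIT",
]

#: identified fundamental kinetic constants of the studied bioreactor
REFERENCE_KINETICS = KineticParameters(
    mu_m=2.1, p_i=0.75, s_m=0.03, s_i=1.0, alpha=0.38, beta=0.002
)
#: identified temperature-coupling constants (start temperature 22 degC)
REFERENCE_COUPLING = TemperatureCoupling(
    k_mu=0.14, k_alpha=0.03, t_theta_cs=0.1, theta_0=22.0
)
#: measured initial loading, harmonised from mg/L to the internal g/L
REFERENCE_INIT = FermentationState(x1=0.0026, x2=0.009, x3=0.0001, x4=22.0)

#: default sensor-noise level as a fraction of the noiseless signal range
DEFAULT_NOISE_FRACTION = 0.02


@dataclass
class MeasuredDataset:
    """A sampled (possibly noisy) CO2 experiment — the identification input.

    ``meta`` carries the generating truth for synthetic data (parameters,
    seed, noise settings) and is empty for data read from disk without a
    metadata sidecar.
    """

    times: np.ndarray
    co2: np.ndarray
    profile: TemperatureProfile
    measured_temp: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.times.shape != self.co2.shape or self.times.ndim != 1:
            raise InvalidInputError("times and co2 must be equal-length 1-D arrays")
        if self.measured_temp is not None:
            self.measured_temp = np.asarray(self.measured_temp, dtype=float)
            if self.measured_temp.shape != self.times.shape:
                raise InvalidInputError("measured_temp must match the sample grid length")
        if not np.all(np.isfinite(self.co2)):
            raise InvalidInputError("co2 series must be finite")
        d = np.diff(self.times)
        if self.times.size >= 2:
            if np.any(d <= 0):
                raise InvalidInputError("sample times must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                raise InvalidInputError("sample times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size >= 2 else np.nan

    def __len__(self) -> int:
        return self.times.size

    def to_dataframe(self):
        import pandas as pd

        data = {
            "time_h": self.times,
            "co2_gL": self.co2,
            "ref_temp_C": self.profile(self.times),
        }
        if self.measured_temp is not None:
            data["temp_C"] = self.measured_temp
        return pd.DataFrame(data)


def lowpass_filter(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Discrete first-order low-pass filter (zero-order-hold discretisation).

    y[k] = y[k-1] + (1 - exp(-dt/tau)) * (x[k] - y[k-1]), with y[0] = x[0].
    ``tau <= 0`` returns the input unchanged.
    """
    if tau <= 0:
        return np.asarray(x, dtype=float).copy()
    a = 1.0 - np.exp(-dt / tau)
    y = np.empty_like(np.asarray(x, dtype=float))
    y[0] = x[0]
    for k in range(1, y.size):
        y[k] = y[k - 1] + a * (x[k] - y[k - 1])
    return y


def generate_experiment(
    params: KineticParameters,
    coupling: TemperatureCoupling,
    init: FermentationState,
    profile: TemperatureProfile,
    t_end: float = DEFAULT_T_END,
    dt_sample: float = DEFAULT_DT_SAMPLE,
    noise_sd: Optional[float] = 0.0,
    filter_tau: float = 0.0,
    seed: Optional[int] = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> MeasuredDataset:
    """Simulate the temperature-considered model and sample it like the lab.

    Gaussian noise of standard deviation ``noise_sd`` (g/L) is added
    independently at each sample; ``noise_sd=None`` uses the default of 2%
    of the noiseless signal range.  With ``filter_tau > 0`` the noisy
    series is passed through a discrete first-order low-pass filter,
    emulating the analog anti-noise filter in the acquisition chain.  The
    generating truth (parameters, seed, noise settings) is recorded in
    ``meta``.
    """
    if dt_sample <= 0:
        raise InvalidInputError("dt_sample must be > 0")
    if noise_sd is not None and noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    if filter_tau < 0:
        raise InvalidInputError("filter_tau must be >= 0")
    n = int(round(t_end / dt_sample))
    times = np.linspace(0.0, n * dt_sample, n + 1)
    traj = simulate(
        params, init, coupling=coupling, profile=profile,
        t_end=float(times[-1]), output_times=times, rtol=rtol, atol=atol,
    )
    truth = traj.x3.copy()
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_FRACTION * float(np.ptp(truth))
    rng = np.random.default_rng(seed)
    co2 = truth + rng.normal(0.0, noise_sd, size=truth.shape) if noise_sd > 0 else truth.copy()
    if filter_tau > 0:
        co2 = lowpass_filter(co2, dt_sample, filter_tau)
    meta = {
        "synthetic": True,
        "params": {k: getattr(params, k) for k in KineticParameters.NAMES},
        "coupling": {k: getattr(coupling, k) for k in TemperatureCoupling.NAMES},
        "init": {"x1": init.x1, "x2": init.x2, "x3": init.x3, "x4": init.x4},
        "profile_breakpoints": list(profile.breakpoints),
        "t_end": float(times[-1]),
        "dt_sample": dt_sample,
        "noise_sd": float(noise_sd),
        "filter_tau": filter_tau,
        "seed": seed,
        "truth_x3": truth,
    }
    return MeasuredDataset(
        times=times, co2=co2, profile=profile, measured_temp=traj.temp, meta=meta
    )


def reference_constant_dataset(
    seed: Optional[int] = None, noise_sd: float = 0.0, filter_tau: float = 0.0
) -> MeasuredDataset:
    """Canonical constant-temperature fixture: reference configuration,
    24 h at constant 22 degC, 10-min sampling (the stage-1 experiment)."""
    return generate_experiment(
        REFERENCE_KINETICS, REFERENCE_COUPLING, REFERENCE_INIT,
        constant_profile(22.0), noise_sd=noise_sd, filter_tau=filter_tau, seed=seed,
    )


def reference_step_dataset(
    step_time: float = 3.0,
    seed: Optional[int] = None,
    noise_sd: float = 0.0,
    filter_tau: float = 0.0,
) -> MeasuredDataset:
    """Canonical step fixture: 22 -> 27 degC at ``step_time`` hours.

    ``step_time=3`` is the stage-2 identification protocol; ``step_time=6``
    is the held-out validation protocol.
    """
    if not (0.0 < step_time < DEFAULT_T_END):
        raise InvalidInputError(f"step_time must lie in (0, {DEFAULT_T_END}) h")
    return generate_experiment(
        REFERENCE_KINETICS, REFERENCE_COUPLING, REFERENCE_INIT,
        make_step_profile(22.0, 27.0, step_time),
        noise_sd=noise_sd, filter_tau=filter_tau, seed=seed,
    )
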