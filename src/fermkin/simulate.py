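"""Trajectory simulation of the fermentation models.

Integrates the 3-state fundamental model or the 4-state
temperature-considered model over a time horizon under a piecewise-constant
reference-temperature protocol.  The reference temperature u(t) is
discontinuous at protocol breakpoints, so integration is restarted at every
breakpoint and each segment sees a constant u — the discontinuity is
resolved exactly rather than smeared by the step controller.

Solver: LSODA (adaptive, switches between Adams and the implicit BDF
method if the problem stiffens; the 0.1 h heating lag is fast against the
multi-hour fermentation scale) through ``scipy.integrate.odeint``, which
has far less per-call overhead than the ``solve_ivp`` wrapper — the
identification stage integrates the model tens of thousands of times.
Defaults rtol 1e-8, atol 1e-10.  Negative concentrations are monitored,
not projected: a state below ``-100*atol`` aborts the run.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import odeint

from .exceptions import IntegrationError, InvalidInputError, RangeError
from .kinetics import FermentationState, KineticParameters, TemperatureCoupling

__all__ = [
    "TemperatureProfile",
    "Trajectory",
    "constant_profile",
    "make_step_profile",
    "evaluate_profile",
    "simulate",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: default output grid spacing: the 10-minute sampling of the CO2 electrode
DEFAULT_DT_SAMPLE = 1.0 / 6.0
#: default experiment horizon: a full kefir fermentation, hours
DEFAULT_T_END = 24.0
#: reference temperatures outside this window are rejected (degC)
DEFAULT_VALIDITY = (4.0, 40.0)


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-constant, right-continuous reference-temperature protocol.

    ``breakpoints`` is an ordered tuple of ``(time_h, temp_C)`` pairs; the
    profile holds each temperature from its breakpoint time (inclusive) to
    the next breakpoint.  The first breakpoint must be at t = 0.
    """

    breakpoints: Tuple[Tuple[float, float], ...]
    validity: Tuple[float, float] = DEFAULT_VALIDITY

    def __post_init__(self) -> None:
        bps = tuple((float(t), float(v)) for t, v in self.breakpoints)
        object.__setattr__(self, "breakpoints", bps)
        if not bps:
            raise InvalidInputError("TemperatureProfile needs at least one breakpoint")
        times = [t for t, _ in bps]
        if times[0] != 0.0:
            raise InvalidInputError(f"first breakpoint must be at t=0, got t={times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidInputError("breakpoint times must be strictly increasing")
        lo, hi = self.validity
        for t, v in bps:
            if not (lo <= v <= hi):
                raise RangeError(
                    f"reference temperature {v} degC at t={t} h outside the "
                    f"validity window [{lo}, {hi}] degC"
                )

    @property
    def times(self) -> Tuple[float, ...]:
        return tuple(t for t, _ in self.breakpoints)

    @property
    def temperatures(self) -> Tuple[float, ...]:
        return tuple(v for _, v in self.breakpoints)

    def value(self, t: float) -> float:
        """Reference temperature at time ``t`` (right-continuous)."""
        if t < 0:
            raise RangeError(f"profile evaluated at negative time t={t}")
        idx = bisect.bisect_right(self.times, t) - 1
        return self.breakpoints[idx][1]

    def __call__(self, t):
        if np.ndim(t) == 0:
            return self.value(float(t))
        return np.array([self.value(float(ti)) for ti in np.asarray(t).ravel()])

    @property
    def is_constant(self) -> bool:
        return len(set(self.temperatures)) == 1

    def segment_edges(self, t_end: float) -> list:
        """Breakpoint times inside (0, t_end) — the solver restart points."""
        return [t for t in self.times if 0.0 < t < t_end]


def constant_profile(theta: float, validity=DEFAULT_VALIDITY) -> TemperatureProfile:
    """Protocol holding one reference temperature for the whole run."""
    return TemperatureProfile(((0.0, theta),), validity)


def make_step_profile(
    theta_start: float, theta_end: float, t_step: float, validity=DEFAULT_VALIDITY
) -> TemperatureProfile:
    """Step protocol: ``theta_start`` on [0, t_step), ``theta_end`` after.

    ``t_step = 0`` degenerates to a constant profile at ``theta_end``; equal
    temperatures degenerate to a constant profile.
    """
    if t_step < 0:
        raise InvalidInputError(f"step time must be >= 0, got {t_step}")
    if t_step == 0:
        return constant_profile(theta_end, validity)
    if theta_start == theta_end:
        return constant_profile(theta_start, validity)
    return TemperatureProfile(((0.0, theta_start), (float(t_step), theta_end)), validity)


def evaluate_profile(profile: TemperatureProfile, t: float) -> float:
    """Functional form of :meth:`TemperatureProfile.value`."""
    return profile.value(t)


@dataclass
class Trajectory:
    """Dense simulated time courses of the fermentation states.

    ``temp`` (bioreactor temperature x4) and ``ref_temp`` (u(t)) are None
    for runs of the 3-state fundamental model without a protocol.
    """

    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    temp: Optional[np.ndarray] = None
    ref_temp: Optional[np.ndarray] = None
    model_tag: str = "fundamental"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise InvalidInputError("trajectory times must be nondecreasing")

    def state_at(self, i: int) -> FermentationState:
        x4 = None if self.temp is None else float(self.temp[i])
        return FermentationState(
            max(float(self.x1[i]), 0.0),
            max(float(self.x2[i]), 0.0),
            max(float(self.x3[i]), 0.0),
            x4,
        )

    def to_dataframe(self):
        import pandas as pd

        data = {"time_h": self.times, "x1_gL": self.x1, "x2_gL": self.x2, "x3_gL": self.x3}
        if self.temp is not None:
            data["temp_C"] = self.temp
        if self.ref_temp is not None:
            data["ref_temp_C"] = self.ref_temp
        return pd.DataFrame(data)

    def plot(self, ax=None):
        """Quick-look plot of the four state time courses."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.x1, label="x1 microorganisms (g/L)")
        ax.plot(self.times, self.x2, label="x2 substrate (g/L)")
        ax.plot(self.times, self.x3, label="x3 dissolved CO2 (g/L)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (g/L)")
        if self.temp is not None:
            ax2 = ax.twinx()
            ax2.plot(self.times, self.temp, color="tab:red", ls="--", label="x4 temp (degC)")
            ax2.set_ylabel("temperature (degC)")
        ax.legend(loc="best")
        return ax


def _fundamental_ode(params: KineticParameters):
    mu_m, p_i, s_m, s_i, alpha, beta = (
        params.mu_m, params.p_i, params.s_m, params.s_i, params.alpha, params.beta,
    )

    def rhs(t, y):
        x1, x2, x3 = y
        phi = mu_m * (1.0 - x3 / p_i) * x2 / (s_m + x2 + x2 * x2 / s_i)
        growth = phi * x1
        return (growth, -growth, (alpha * phi + beta) * x1)

    return rhs


def _temperature_ode(params: KineticParameters, coupling: TemperatureCoupling, u: float):
    mu_m, p_i, s_m, s_i, alpha, beta = (
        params.mu_m, params.p_i, params.s_m, params.s_i, params.alpha, params.beta,
    )
    k_mu, k_alpha, tcs, th0 = (
        coupling.k_mu, coupling.k_alpha, coupling.t_theta_cs, coupling.theta_0,
    )

    def rhs(t, y):
        x1, x2, x3, x4 = y
        dev = x4 - th0
        mu_theta = mu_m * (1.0 + k_mu * dev)
        alpha_theta = alpha * (1.0 + k_alpha * dev)
        if mu_theta <= 0 or alpha_theta <= 0:
            which = "mu_m" if mu_theta <= 0 else "alpha"
            raise RangeError(
                f"temperature-adjusted {which} non-positive at t={t:.4g} h "
                f"(x4={x4:.4g} degC)"
            )
        phi = mu_theta * (1.0 - x3 / p_i) * x2 / (s_m + x2 + x2 * x2 / s_i)
        growth = phi * x1
        return (growth, -growth, (alpha_theta * phi + beta) * x1, (u - x4) / tcs)

    return rhs


def simulate(
    params: KineticParameters,
    init: FermentationState,
    *,
    coupling: Optional[TemperatureCoupling] = None,
    profile: Optional[TemperatureProfile] = None,
    t_end: float = DEFAULT_T_END,
    output_times: Optional[Sequence[float]] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate a fermentation model and sample it on an output grid.

    Parameters
    ----------
    params, init
        Kinetic constants and initial state.  With ``coupling=None`` the
        3-state fundamental model is integrated and any profile is ignored
        (the fundamental model is autonomous).  With a coupling, ``init``
        must carry an initial temperature ``x4`` and ``profile`` supplies
        the reference temperature; a missing profile defaults to constant
        ``u = x4(0)``.
    t_end
        Horizon in hours (> 0).
    output_times
        Strictly within ``[0, t_end]``; defaults to 10-min sampling.

    Returns
    -------
    Trajectory
        States evaluated at ``output_times``; integration is restarted at
        every profile breakpoint so the discontinuous u(t) is exact.
    """
    if t_end <= 0:
        raise InvalidInputError(f"t_end must be > 0, got {t_end}")
    if output_times is None:
        n = int(round(t_end / DEFAULT_DT_SAMPLE))
        output_times = np.linspace(0.0, t_end, n + 1)
    output_times = np.asarray(output_times, dtype=float)
    if output_times.size == 0:
        raise InvalidInputError("output_times must be non-empty")
    if np.any(np.diff(output_times) <= 0):
        raise InvalidInputError("output_times must be strictly increasing")
    if output_times[0] < 0 or output_times[-1] > t_end * (1 + 1e-12):
        raise InvalidInputError("output_times must lie within [0, t_end]")

    four_state = coupling is not None
    if four_state:
        if init.x4 is None:
            raise InvalidInputError("temperature-considered simulation needs init.x4")
        if profile is None:
            profile = constant_profile(init.x4)
        edges = [0.0] + profile.segment_edges(t_end) + [t_end]
        model_tag = "temperature_considered"
    else:
        edges = [0.0, t_end]
        model_tag = "fundamental"

    y = init.as_array() if four_state else np.array([init.x1, init.x2, init.x3])
    out_states = np.empty((len(output_times), y.size))
    filled = np.zeros(len(output_times), dtype=bool)

    for a, b in zip(edges, edges[1:]):
        if four_state:
            u = profile.value(a)
            rhs = _temperature_ode(params, coupling, u)
        else:
            rhs = _fundamental_ode(params)
        last = b >= edges[-1]
        # sample points owned by this segment: [a, b) plus b on the last one
        mask = (output_times >= a) & ((output_times <= b) if last else (output_times < b))
        t_eval = np.unique(np.concatenate([[a], output_times[mask], [b]]))
        try:
            ys, info = odeint(
                rhs, y, t_eval, tfirst=True, rtol=rtol, atol=atol,
                mxstep=100_000, full_output=True, printmessg=False,
            )
        except RangeError as err:
            raise RangeError(f"{err} (during integration of segment [{a}, {b}] h)") from err
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"ODE solver failed on segment [{a}, {b}] h: {info['message']}"
            )
        if np.min(ys[:, :3]) < -100.0 * atol:
            raise IntegrationError(
                f"concentration fell below -100*atol on segment [{a}, {b}] h "
                f"(min {np.min(ys[:, :3]):.3e} g/L)"
            )
        idx = np.searchsorted(t_eval, output_times[mask])
        out_states[mask] = ys[idx]
        filled |= mask
        y = ys[-1]

    if not np.all(filled):  # pragma: no cover - defensive
        raise IntegrationError("internal error: output grid not fully covered")

    temp = out_states[:, 3] if four_state else None
    ref = profile(output_times) if (four_state and profile is not None) else None
    return Trajectory(
        times=output_times,
        x1=out_states[:, 0],
        x2=out_states[:, 1],
        x3=out_states[:, 2],
        temp=temp,
        ref_temp=ref,
        model_tag=model_tag,
        meta={"rtol": rtol, "atol": atol, "method": "LSODA"},
    )
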