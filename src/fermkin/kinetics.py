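"""Kinetic core of the batch milk-fermentation model.

The fermentation of milk (kefir) in a closed batch bioreactor is described
by three coupled mass balances: microorganism concentration ``x1``,
substrate concentration ``x2`` and dissolved-CO2 (fermentation product)
concentration ``x3``, all in g/L.  The specific growth rate combines
product inhibition, Monod-type substrate saturation and substrate
inhibition:

    phi(x2, x3) = mu_m * (1 - x3/P_i) * x2 / (S_m + x2 + x2^2/S_i)

and the fundamental (autonomous, constant-temperature) model reads

    dx1/dt =  phi * x1
    dx2/dt = -phi * x1
    dx3/dt = (alpha * phi + beta) * x1

The temperature-considered extension adds the bioreactor temperature
``x4`` (degC) as a fourth state following a first-order lag toward the
reference temperature ``u(t)`` of the heating/cooling system,

    dx4/dt = (u - x4) / T_theta_cs,

and makes ``mu_m`` and ``alpha`` linear functions of the temperature
deviation from the start-of-fermentation temperature ``theta_0``:

    mu_m_theta(x4) = mu_m  * (1 + k_mu    * (x4 - theta_0))
    alpha_theta(x4) = alpha * (1 + k_alpha * (x4 - theta_0))

Both temperature-dependent factors multiply inside the product balance
(dx3/dt uses ``alpha_theta * phi_theta``), exactly as the model is posed.

Everything here is pure computation on plain floats; integration lives in
:mod:`fermkin.simulate`, serialization in :mod:`fermkin.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Tuple

import numpy as np

from .exceptions import InvalidInputError, RangeError

__all__ = [
    "KineticParameters",
    "TemperatureCoupling",
    "FermentationState",
    "StateDerivative",
    "growth_rate_factor",
    "fundamental_rhs",
    "temperature_adjusted_params",
    "temperature_considered_rhs",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """The six constants of the fundamental kinetic model.

    Attributes
    ----------
    mu_m : float
        Maximum microorganisms' growth rate, h^-1.
    p_i : float
        Product inhibition constant, g/L; growth stops when x3 reaches it.
    s_m : float
        Substrate saturation constant, g/L.
    s_i : float
        Substrate inhibition constant, g/L.
    alpha : float
        Product yield tied to microbial growth, (g/L)/(g/L), dimensionless.
    beta : float
        Growth-independent product formation rate, h^-1.
    """

    mu_m: float
    p_i: float
    s_m: float
    s_i: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require_finite(f.name, v)
            if v <= 0:
                raise InvalidInputError(
                    f"kinetic parameter {f.name} must be strictly positive, got {v!r}"
                )

    NAMES = ("mu_m", "p_i", "s_m", "s_i", "alpha", "beta")
    UNITS = ("h^-1", "g/L", "g/L", "g/L", "g/L per g/L", "h^-1")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu_m, self.p_i, self.s_m, self.s_i, self.alpha, self.beta])

    @classmethod
    def from_array(cls, vec) -> "KineticParameters":
        return cls(*(float(v) for v in vec))

    def replace(self, **kwargs) -> "KineticParameters":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kwargs)
        return KineticParameters(**d)


@dataclass(frozen=True)
class TemperatureCoupling:
    """Constants of the temperature extension.

    Attributes
    ----------
    k_mu : float
        Temperature coefficient on mu_m, (degC)^-1.  Zero disables coupling.
    k_alpha : float
        Temperature coefficient on alpha, (degC)^-1.
    t_theta_cs : float
        Time constant of the controlled heating system, h; must be > 0.
    theta_0 : float
        Content temperature at fermentation start, degC; the linearisation
        point of the temperature laws.
    """

    k_mu: float
    k_alpha: float
    t_theta_cs: float
    theta_0: float

    NAMES = ("k_mu", "k_alpha", "t_theta_cs", "theta_0")
    UNITS = ("(degC)^-1", "(degC)^-1", "h", "degC")

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_finite(f.name, getattr(self, f.name))
        if self.t_theta_cs <= 0:
            raise InvalidInputError(
                f"heating time constant t_theta_cs must be > 0, got {self.t_theta_cs!r}"
            )


@dataclass(frozen=True)
class FermentationState:
    """Instantaneous state of the fermentation.

    ``x4`` (bioreactor temperature, degC) is ``None`` for the 3-state
    fundamental model.
    """

    x1: float
    x2: float
    x3: float
    x4: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v < 0:
                raise InvalidInputError(f"concentration {name} must be >= 0, got {v!r}")
        if self.x4 is not None:
            _require_finite("x4", self.x4)

    @property
    def has_temperature(self) -> bool:
        return self.x4 is not None

    def as_array(self) -> np.ndarray:
        if self.x4 is None:
            return np.array([self.x1, self.x2, self.x3])
        return np.array([self.x1, self.x2, self.x3, self.x4])


@dataclass(frozen=True)
class StateDerivative:
    """Time derivative of a :class:`FermentationState` (g/L/h, degC/h)."""

    dx1: float
    dx2: float
    dx3: float
    dx4: Optional[float] = None


def growth_rate_factor(x2: float, x3: float, params: KineticParameters):
    """Specific growth rate phi(x2, x3), h^-1.

    phi = mu_m * (1 - x3/P_i) * x2 / (S_m + x2 + x2^2/S_i).

    Accepts scalars or numpy arrays.  May be negative once the product
    concentration exceeds the inhibition constant (dying phase); the
    inhibition term is deliberately not floored at zero.
    """
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    if not (np.all(np.isfinite(x2)) and np.all(np.isfinite(x3))):
        raise InvalidInputError("growth_rate_factor requires finite x2, x3")
    if np.any(x2 < 0):
        raise InvalidInputError("substrate concentration x2 must be >= 0")
    phi = params.mu_m * (1.0 - x3 / params.p_i) * x2 / (
        params.s_m + x2 + x2 * x2 / params.s_i
    )
    return float(phi) if phi.ndim == 0 else phi


def fundamental_rhs(state: FermentationState, params: KineticParameters) -> StateDerivative:
    """Right-hand side of the 3-state fundamental model.

    dx2 is computed as the exact negation of dx1, so dx1 + dx2 == 0
    bitwise and x1 + x2 is a conserved quantity of the model.
    """
    phi = growth_rate_factor(state.x2, state.x3, params)
    growth = phi * state.x1
    return StateDerivative(
        dx1=growth,
        dx2=-growth,
        dx3=(params.alpha * phi + params.beta) * state.x1,
    )


def temperature_adjusted_params(
    x4: float, params: KineticParameters, coupling: TemperatureCoupling
) -> Tuple[float, float]:
    """Temperature-dependent (mu_m_theta, alpha_theta) at temperature ``x4``.

    Linear laws around theta_0; valid only while both adjusted values stay
    positive.  A non-positive value means the linearisation was driven out
    of its validity range and raises :class:`RangeError` (clamping would
    silently corrupt identification objectives).
    """
    _require_finite("x4", x4)
    dev = x4 - coupling.theta_0
    mu_m_theta = params.mu_m * (1.0 + coupling.k_mu * dev)
    alpha_theta = params.alpha * (1.0 + coupling.k_alpha * dev)
    if mu_m_theta <= 0:
        raise RangeError(
            f"temperature-adjusted mu_m is non-positive ({mu_m_theta:.4g}) "
            f"at x4={x4:.4g} degC; linear temperature law out of validity"
        )
    if alpha_theta <= 0:
        raise RangeError(
            f"temperature-adjusted alpha is non-positive ({alpha_theta:.4g}) "
            f"at x4={x4:.4g} degC; linear temperature law out of validity"
        )
    return mu_m_theta, alpha_theta


def temperature_considered_rhs(
    state: FermentationState,
    u: float,
    params: KineticParameters,
    coupling: TemperatureCoupling,
) -> StateDerivative:
    """Right-hand side of the 4-state temperature-considered model.

    The concentration balances are the fundamental model with (mu_m, alpha)
    replaced by their temperature-adjusted values at the current bioreactor
    temperature ``x4``; the temperature state relaxes toward the reference
    ``u`` with time constant ``t_theta_cs``.
    """
    if state.x4 is None:
        raise InvalidInputError("temperature_considered_rhs needs a 4-state input (x4 set)")
    _require_finite("u", u)
    mu_m_theta, alpha_theta = temperature_adjusted_params(state.x4, params, coupling)
    phi = growth_rate_factor(
        state.x2, state.x3, params.replace(mu_m=mu_m_theta)
    )
    growth = phi * state.x1
    return StateDerivative(
        dx1=growth,
        dx2=-growth,
        dx3=(alpha_theta * phi + params.beta) * state.x1,
        dx4=(u - state.x4) / coupling.t_theta_cs,
    )
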