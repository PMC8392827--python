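"""Parameter identification from measured CO2 trajectories.

The identification objective is the integral absolute error (IAE) between
the measured dissolved-CO2 series and the model's x3 channel on the sample
grid; only the CO2 channel is fitted.  The optimizer is a bound-constrained
global-best particle swarm with adaptive inertia — the classic variant with
the modifications found in mainstream scientific-computing toolboxes:

* inertia weight adapted within ``inertia_range`` by a stall counter
  (doubled while the swarm keeps improving, halved after repeated stalls),
* self/social acceleration 1.49 each,
* velocities clamped to the box width, reflective bound handling,
* stopping when the relative change of the best objective over a window of
  ``stall_iterations`` iterations falls below ``function_tolerance``
  (relative to ``max(1, |best|)``), or at ``max_iterations``.

The IAE objective is nearly degenerate along curved parameter ridges
(mu_m trades off against S_m and P_i, the heating time constant against
the coupling gains), so the stage defaults use large swarms — 600
particles for the 6-parameter stage, 150 for the 3-parameter stage.
Smaller swarms routinely collapse onto a compensation ridge and return a
visually perfect fit with badly biased parameters; the large swarm keeps
enough diversity to locate the global basin before contraction.

Identification is split in two stages, mirroring how the experiments are
run: stage 1 fits the six fundamental kinetic constants on a
constant-temperature experiment (where the temperature extension is inert);
stage 2 freezes those and fits the three temperature-coupling constants
(k_mu, k_alpha, t_theta_cs) on a step-temperature experiment, with theta_0
pinned to the initial temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

from .exceptions import InvalidInputError, OptimizationError
from .kinetics import FermentationState, KineticParameters, TemperatureCoupling
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, simulate

__all__ = [
    "PSOConfig",
    "IdentificationResult",
    "TwoStageResult",
    "iae",
    "pso_minimize",
    "identify_stage1",
    "identify_stage2",
    "identify_two_stage",
    "STAGE1_BOUNDS",
    "STAGE2_BOUNDS",
]

logger = logging.getLogger(__name__)

#: broad stage-1 search box, deliberately not centred on any known values
STAGE1_BOUNDS: Dict[str, Tuple[float, float]] = {
    "mu_m": (0.1, 10.0),
    "p_i": (0.01, 5.0),
    "s_m": (1e-4, 1.0),
    "s_i": (0.01, 10.0),
    "alpha": (0.01, 2.0),
    "beta": (1e-5, 0.1),
}

#: stage-2 search box for the temperature-coupling constants
STAGE2_BOUNDS: Dict[str, Tuple[float, float]] = {
    "k_mu": (0.0, 1.0),
    "k_alpha": (0.0, 0.5),
    "t_theta_cs": (0.01, 1.0),
}

#: default swarm sizes per stage (see module docstring)
STAGE1_SWARM = 600
STAGE2_SWARM = 150


def iae(measured_co2, simulated_co2, grid) -> float:
    """Integral absolute error between two CO2 series, g*h/L.

    Trapezoidal integral of |measured - simulated| over the common time
    grid.  Zero iff the series are identical; exact for piecewise-linear
    integrands.
    """
    m = np.asarray(measured_co2, dtype=float)
    s = np.asarray(simulated_co2, dtype=float)
    t = np.asarray(grid, dtype=float)
    if m.shape != s.shape or m.shape != t.shape or m.ndim != 1:
        raise InvalidInputError(
            f"iae needs three equal-length 1-D series, got shapes "
            f"{m.shape}, {s.shape}, {t.shape}"
        )
    if t.size < 2:
        raise InvalidInputError("iae needs at least 2 grid points")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("iae grid must be strictly increasing")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(s))):
        raise InvalidInputError("iae series must be finite")
    return float(np.trapezoid(np.abs(m - s), t))


@dataclass
class PSOConfig:
    """Particle-swarm settings.

    ``swarm_size=None`` defaults to 10x the problem dimension.  ``bounds``
    may be left None when the calling stage supplies its own box.
    """

    swarm_size: Optional[int] = None
    inertia_range: Tuple[float, float] = (0.1, 1.1)
    self_weight: float = 1.49
    social_weight: float = 1.49
    max_iterations: int = 500
    stall_iterations: int = 20
    function_tolerance: float = 1e-6
    bounds: Optional[Sequence[Tuple[float, float]]] = None
    seed: Optional[int] = None
    max_nonfinite_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.swarm_size is not None and self.swarm_size < 2:
            raise InvalidInputError("swarm_size must be >= 2")
        lo, hi = self.inertia_range
        if not (0 <= lo <= hi):
            raise InvalidInputError("inertia_range must satisfy 0 <= min <= max")
        if self.function_tolerance <= 0:
            raise InvalidInputError("function_tolerance must be > 0")
        if self.stall_iterations < 1 or self.max_iterations < 1:
            raise InvalidInputError("iteration counts must be >= 1")
        if self.bounds is not None:
            b = [(float(a), float(c)) for a, c in self.bounds]
            for a, c in b:
                if not (np.isfinite(a) and np.isfinite(c) and a < c):
                    raise InvalidInputError(f"bounds must be finite with lower < upper, got {(a, c)}")
            self.bounds = b


@dataclass
class IdentificationResult:
    """Outcome of one PSO run.

    ``estimate`` is the typed parameter object for the stage wrappers and
    the raw numpy vector for :func:`pso_minimize`; ``history`` is the best
    objective after every iteration (nonincreasing), whose last entry
    equals ``objective_value``.
    """

    estimate: object
    x: np.ndarray
    objective_value: float
    iterations: int
    history: np.ndarray
    seed: Optional[int]
    n_evaluations: int = 0
    bounds: Optional[Sequence[Tuple[float, float]]] = None
    parameter_names: Optional[Tuple[str, ...]] = None


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    config: PSOConfig,
    *,
    callback: Optional[Callable[[int, float], None]] = None,
) -> IdentificationResult:
    """Minimise ``objective`` over the box ``config.bounds``.

    Objective exceptions and non-finite returns are treated as +inf; if
    more than ``config.max_nonfinite_fraction`` of all evaluations are
    non-finite the search aborts with :class:`OptimizationError`.
    """
    if config.bounds is None:
        raise InvalidInputError("pso_minimize requires config.bounds")
    lb = np.array([b[0] for b in config.bounds])
    ub = np.array([b[1] for b in config.bounds])
    dim = lb.size
    width = ub - lb
    n = config.swarm_size if config.swarm_size is not None else 10 * dim
    rng = np.random.default_rng(config.seed)
    w_min, w_max = config.inertia_range
    c1, c2 = config.self_weight, config.social_weight

    X = lb + rng.random((n, dim)) * width
    V = (2.0 * rng.random((n, dim)) - 1.0) * width

    n_evals = 0
    n_bad = 0

    def f(x: np.ndarray) -> float:
        nonlocal n_evals, n_bad
        n_evals += 1
        try:
            val = float(objective(x))
        except (ArithmeticError, ValueError, RuntimeError):
            val = np.inf
        if not np.isfinite(val):
            n_bad += 1
            val = np.inf
        return val

    F = np.array([f(x) for x in X])
    pbest_x = X.copy()
    pbest_f = F.copy()
    g = int(np.argmin(pbest_f))
    gbest_x = pbest_x[g].copy()
    gbest_f = float(pbest_f[g])

    history = [gbest_f]
    w = w_max
    stall_counter = 0
    iterations = 0
    window = config.stall_iterations

    for it in range(1, config.max_iterations + 1):
        r1 = rng.random((n, dim))
        r2 = rng.random((n, dim))
        V = w * V + c1 * r1 * (pbest_x - X) + c2 * r2 * (gbest_x - X)
        np.clip(V, -width, width, out=V)
        X = X + V
        # reflective bounds: fold back across the violated face, reverse velocity
        for bound, mask_fn in ((lb, np.less), (ub, np.greater)):
            mask = mask_fn(X, bound)
            if np.any(mask):
                X[mask] = 2.0 * np.broadcast_to(bound, X.shape)[mask] - X[mask]
                V[mask] = -V[mask]
        np.clip(X, lb, ub, out=X)

        F = np.array([f(x) for x in X])
        improved_mask = F < pbest_f
        pbest_x[improved_mask] = X[improved_mask]
        pbest_f[improved_mask] = F[improved_mask]
        g = int(np.argmin(pbest_f))
        improved = pbest_f[g] < gbest_f
        if improved:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
            stall_counter = max(0, stall_counter - 1)
        else:
            stall_counter += 1
        if stall_counter < 2:
            w = min(2.0 * w, w_max)
        elif stall_counter > 5:
            w = max(w / 2.0, w_min)

        history.append(gbest_f)
        iterations = it
        if callback is not None:
            callback(it, gbest_f)
        logger.debug("pso iteration %d best objective %.6e", it, gbest_f)

        if n_bad > config.max_nonfinite_fraction * n_evals and n_evals >= 2 * n:
            raise OptimizationError(
                f"objective non-finite on {n_bad}/{n_evals} evaluations; "
                "check bounds and model validity"
            )
        if len(history) > window:
            recent = history[-(window + 1):]
            f_old, f_new = max(recent), min(recent)
            if (f_old - f_new) / max(1.0, abs(f_new)) < config.function_tolerance:
                break

    return IdentificationResult(
        estimate=gbest_x.copy(),
        x=gbest_x.copy(),
        objective_value=gbest_f,
        iterations=iterations,
        history=np.array(history),
        seed=config.seed,
        n_evaluations=n_evals,
        bounds=list(config.bounds),
    )


def _dataset_grid(dataset) -> np.ndarray:
    times = np.asarray(dataset.times, dtype=float)
    if times.size < 2:
        raise InvalidInputError("dataset must contain at least 2 samples")
    return times


def _with_defaults(config: Optional[PSOConfig], swarm: int, bounds) -> PSOConfig:
    cfg = PSOConfig() if config is None else replace(config)
    if cfg.bounds is None:
        cfg.bounds = list(bounds)
    if cfg.swarm_size is None:
        cfg.swarm_size = swarm
    return cfg


def identify_stage1(
    dataset,
    init: FermentationState,
    config: Optional[PSOConfig] = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    callback=None,
) -> IdentificationResult:
    """Stage 1: fit the six fundamental constants on a constant-T run.

    Minimises the IAE between the measured CO2 and the fundamental model's
    x3 over (mu_m, p_i, s_m, s_i, alpha, beta) within :data:`STAGE1_BOUNDS`.
    The dataset's temperature protocol must be constant; initial
    concentrations are treated as known (measured), not identified.
    """
    times = _dataset_grid(dataset)
    if dataset.profile is not None and not dataset.profile.is_constant:
        raise InvalidInputError(
            "stage 1 requires a constant-temperature dataset; got a protocol "
            f"with temperatures {dataset.profile.temperatures}"
        )
    co2 = np.asarray(dataset.co2, dtype=float)
    names = KineticParameters.NAMES
    cfg = _with_defaults(config, STAGE1_SWARM, [STAGE1_BOUNDS[k] for k in names])
    init3 = FermentationState(init.x1, init.x2, init.x3)
    t_end = float(times[-1])

    def objective(vec: np.ndarray) -> float:
        params = KineticParameters(*vec)
        traj = simulate(
            params, init3, t_end=t_end, output_times=times, rtol=rtol, atol=atol
        )
        return iae(co2, traj.x3, times)

    res = pso_minimize(objective, cfg, callback=callback)
    res.estimate = KineticParameters(*res.x)
    res.parameter_names = names
    return res


def identify_stage2(
    dataset,
    stage1_params: KineticParameters,
    init: FermentationState,
    config: Optional[PSOConfig] = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    callback=None,
) -> IdentificationResult:
    """Stage 2: fit (k_mu, k_alpha, t_theta_cs) on a step-temperature run.

    The six fundamental constants are held fixed at ``stage1_params``
    throughout, and theta_0 is pinned to the protocol's initial
    temperature (the content temperature at fermentation start); the
    coupling is unidentifiable from a constant-temperature experiment, so
    such a dataset is rejected.
    """
    times = _dataset_grid(dataset)
    if dataset.profile is None or dataset.profile.is_constant:
        raise InvalidInputError(
            "stage 2 requires a dataset with at least one temperature change; "
            "the coupling constants are unidentifiable at constant temperature"
        )
    co2 = np.asarray(dataset.co2, dtype=float)
    theta_0 = dataset.profile.value(0.0)
    x4_0 = init.x4 if init.x4 is not None else theta_0
    init4 = FermentationState(init.x1, init.x2, init.x3, x4_0)
    names = ("k_mu", "k_alpha", "t_theta_cs")
    cfg = _with_defaults(config, STAGE2_SWARM, [STAGE2_BOUNDS[k] for k in names])
    t_end = float(times[-1])
    profile = dataset.profile

    def objective(vec: np.ndarray) -> float:
        coupling = TemperatureCoupling(vec[0], vec[1], vec[2], theta_0)
        traj = simulate(
            stage1_params, init4, coupling=coupling, profile=profile,
            t_end=t_end, output_times=times, rtol=rtol, atol=atol,
        )
        return iae(co2, traj.x3, times)

    res = pso_minimize(objective, cfg, callback=callback)
    res.estimate = TemperatureCoupling(res.x[0], res.x[1], res.x[2], theta_0)
    res.parameter_names = names
    return res


@dataclass
class TwoStageResult:
    """Full nine-parameter identification outcome."""

    kinetics: KineticParameters
    coupling: TemperatureCoupling
    stage1: IdentificationResult
    stage2: IdentificationResult
    report: dict = field(default_factory=dict)


def identify_two_stage(
    dataset_const,
    dataset_step,
    init: FermentationState,
    config1: Optional[PSOConfig] = None,
    config2: Optional[PSOConfig] = None,
    **kwargs,
) -> TwoStageResult:
    """Run stage 1 on the constant-T dataset, then stage 2 on the step one.

    Returns the combined estimate plus a report carrying both convergence
    histories and final IAE values.
    """
    s1 = identify_stage1(dataset_const, init, config1, **kwargs)
    s2 = identify_stage2(dataset_step, s1.estimate, init, config2, **kwargs)
    report = {
        "stage1_iae": s1.objective_value,
        "stage2_iae": s2.objective_value,
        "stage1_iterations": s1.iterations,
        "stage2_iterations": s2.iterations,
        "stage1_history": s1.history,
        "stage2_history": s2.history,
    }
    return TwoStageResult(
        kinetics=s1.estimate, coupling=s2.estimate, stage1=s1, stage2=s2, report=report
    )
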