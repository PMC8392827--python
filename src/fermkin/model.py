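"""Model/Results facade for the two-stage identification workflow.

``FermentationModel`` is constructed from the measured experiments (a
constant-temperature run, and optionally a step-temperature run) plus the
known initial loading; ``fit()`` runs the staged particle-swarm
identification and returns a ``FermentationResults`` object carrying the
nine parameter estimates, the final IAE objectives, the convergence
histories and a ``summary()`` table.  Simulation under the fitted model
and a quick fit plot hang off the results object.

Typical use::

    from fermkin import FermentationModel, reference_constant_dataset, \
        reference_step_dataset, REFERENCE_INIT

    model = FermentationModel(
        reference_constant_dataset(), reference_step_dataset(3.0),
        init=REFERENCE_INIT,
    )
    res = model.fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import MeasuredDataset
from .exceptions import InvalidInputError
from .identify import (
    PSOConfig,
    IdentificationResult,
    identify_stage1,
    identify_stage2,
)
from .kinetics import FermentationState, KineticParameters, TemperatureCoupling
from .simulate import Trajectory, simulate

__all__ = ["FermentationModel", "FermentationResults"]


class FermentationModel:
    """Temperature-considered fermentation model bound to measured data.

    Parameters
    ----------
    dataset_const : MeasuredDataset
        Constant-temperature CO2 experiment (stage-1 input).
    dataset_step : MeasuredDataset, optional
        Step-temperature experiment (stage-2 input).  Without it, ``fit``
        estimates only the six fundamental constants.
    init : FermentationState
        Measured initial loading (known, not identified).
    config_stage1, config_stage2 : PSOConfig, optional
        Swarm settings per stage; sensible defaults otherwise (swarm 60
        for stage 1, 30 for stage 2).
    """

    def __init__(
        self,
        dataset_const: MeasuredDataset,
        dataset_step: Optional[MeasuredDataset] = None,
        *,
        init: FermentationState,
        config_stage1: Optional[PSOConfig] = None,
        config_stage2: Optional[PSOConfig] = None,
    ) -> None:
        if dataset_const.profile is not None and not dataset_const.profile.is_constant:
            raise InvalidInputError("dataset_const must be a constant-temperature run")
        if dataset_step is not None and dataset_step.profile.is_constant:
            raise InvalidInputError("dataset_step must contain a temperature change")
        self.dataset_const = dataset_const
        self.dataset_step = dataset_step
        self.init = init
        self.config_stage1 = config_stage1
        self.config_stage2 = config_stage2

    @classmethod
    def from_csv(cls, const_path, step_path=None, *, init: FermentationState, **kwargs):
        """Build a model from dataset CSV files (see :mod:`fermkin.io`)."""
        from .io import read_dataset

        ds_const = read_dataset(const_path)
        ds_step = read_dataset(step_path) if step_path is not None else None
        return cls(ds_const, ds_step, init=init, **kwargs)

    def fit(self, seed: Optional[int] = None, *, callback=None) -> "FermentationResults":
        """Run the staged identification; returns :class:`FermentationResults`.

        ``seed`` seeds both swarms (stage 2 uses ``seed + 1`` so the stages
        draw independent streams while staying reproducible).
        """
        cfg1 = self.config_stage1 or PSOConfig()
        if seed is not None:
            cfg1 = PSOConfig(**{**cfg1.__dict__, "seed": seed})
        s1 = identify_stage1(self.dataset_const, self.init, cfg1, callback=callback)
        s2 = None
        if self.dataset_step is not None:
            cfg2 = self.config_stage2 or PSOConfig()
            if seed is not None:
                cfg2 = PSOConfig(**{**cfg2.__dict__, "seed": seed + 1})
            s2 = identify_stage2(
                self.dataset_step, s1.estimate, self.init, cfg2, callback=callback
            )
        return FermentationResults(model=self, stage1=s1, stage2=s2, seed=seed)


@dataclass
class FermentationResults:
    """Fitted parameters, objectives and diagnostics of one identification."""

    model: FermentationModel
    stage1: IdentificationResult
    stage2: Optional[IdentificationResult]
    seed: Optional[int]

    @property
    def kinetics(self) -> KineticParameters:
        return self.stage1.estimate

    @property
    def coupling(self) -> Optional[TemperatureCoupling]:
        return None if self.stage2 is None else self.stage2.estimate

    @property
    def params(self) -> pd.Series:
        """All estimated parameters as a named series."""
        k = self.kinetics
        data = {name: getattr(k, name) for name in KineticParameters.NAMES}
        if self.coupling is not None:
            c = self.coupling
            data.update({n: getattr(c, n) for n in ("k_mu", "k_alpha", "t_theta_cs")})
        return pd.Series(data)

    def simulate(self, profile=None, *, t_end: Optional[float] = None,
                 output_times=None) -> Trajectory:
        """Simulate the fitted model; with a profile and a fitted coupling
        the 4-state model is used, otherwise the fundamental one."""
        init = self.model.init
        if t_end is None:
            t_end = float(self.model.dataset_const.times[-1])
        if self.coupling is not None and profile is not None:
            return simulate(self.kinetics, init, coupling=self.coupling,
                            profile=profile, t_end=t_end, output_times=output_times)
        init3 = FermentationState(init.x1, init.x2, init.x3)
        return simulate(self.kinetics, init3, t_end=t_end, output_times=output_times)

    def summary(self) -> str:
        """Human-readable identification report."""
        lines = [
            "Two-stage PSO identification of the temperature-considered",
            "batch-fermentation model (IAE objective, CO2 channel only)",
            "=" * 62,
            f"{'parameter':<12}{'estimate':>14}  unit",
            "-" * 62,
        ]
        k = self.kinetics
        for name, unit in zip(KineticParameters.NAMES, KineticParameters.UNITS):
            lines.append(f"{name:<12}{getattr(k, name):>14.5g}  {unit}")
        if self.coupling is not None:
            c = self.coupling
            for name, unit in zip(TemperatureCoupling.NAMES, TemperatureCoupling.UNITS):
                tag = "  (fixed)" if name == "theta_0" else ""
                lines.append(f"{name:<12}{getattr(c, name):>14.5g}  {unit}{tag}")
        lines.append("-" * 62)
        lines.append(
            f"stage 1: IAE {self.stage1.objective_value:.4e} g*h/L in "
            f"{self.stage1.iterations} iterations "
            f"({self.stage1.n_evaluations} model evaluations)"
        )
        if self.stage2 is not None:
            lines.append(
                f"stage 2: IAE {self.stage2.objective_value:.4e} g*h/L in "
                f"{self.stage2.iterations} iterations "
                f"({self.stage2.n_evaluations} model evaluations)"
            )
        lines.append(f"seed: {self.seed}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "parameters": {k: float(v) for k, v in self.params.items()},
            "stage1": {
                "iae": self.stage1.objective_value,
                "iterations": self.stage1.iterations,
            },
            "seed": self.seed,
        }
        if self.stage2 is not None:
            payload["stage2"] = {
                "iae": self.stage2.objective_value,
                "iterations": self.stage2.iterations,
            }
        return json.dumps(payload, indent=2)

    def plot_fit(self, ax=None):
        """Measured CO2 vs fitted-model x3 for the available datasets."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ds = self.model.dataset_const
        ax.plot(ds.times, ds.co2, ".", ms=3, label="measured (constant T)")
        ax.plot(ds.times, self.simulate(output_times=ds.times).x3,
                label="fitted model (constant T)")
        if self.model.dataset_step is not None and self.coupling is not None:
            ds2 = self.model.dataset_step
            ax.plot(ds2.times, ds2.co2, ".", ms=3, label="measured (step T)")
            traj = self.simulate(ds2.profile, t_end=float(ds2.times[-1]),
                                 output_times=ds2.times)
            ax.plot(ds2.times, traj.x3, label="fitted model (step T)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("dissolved CO2 (g/L)")
        ax.legend()
        return ax

    def convergence_history(self) -> pd.DataFrame:
        """Long-format best-IAE-per-iteration table for both stages."""
        frames = [pd.DataFrame({
            "stage": 1,
            "iteration": np.arange(len(self.stage1.history)),
            "best_iae": self.stage1.history,
        })]
        if self.stage2 is not None:
            frames.append(pd.DataFrame({
                "stage": 2,
                "iteration": np.arange(len(self.stage2.history)),
                "best_iae": self.stage2.history,
            }))
        return pd.concat(frames, ignore_index=True)
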