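# fermkin

Temperature-aware kinetic modelling of dissolved-CO₂ production during
milk (kefir) fermentation in a batch bioreactor, with two-stage particle-
swarm identification of all model constants from measured CO₂ time
courses.

## The problem

A batch bioreactor is closed: once loaded, nothing can be added or
removed, so the classical 3-state fermentation model is autonomous —
microorganisms `x1`, substrate `x2` and dissolved CO₂ `x3` (all g/L)
evolve from their initial values alone:

```
ẋ1 =  φ(x2, x3) · x1            φ(x2, x3) = μm (1 − x3/Pᵢ) x2 / (Sm + x2 + x2²/Sᵢ)
ẋ2 = −φ(x2, x3) · x1
ẋ3 = (α φ(x2, x3) + β) · x1
```

with product inhibition (`Pᵢ`), Monod saturation (`Sm`) and substrate
inhibition (`Sᵢ`). The one thing an operator *can* manipulate during a
run is temperature. The temperature-considered model adds the bioreactor
temperature `x4` (°C) as a fourth state following a first-order lag
toward the heating-system reference `u(t)` with time constant `T_θcs`,
and makes the growth rate and growth-associated yield linear in the
temperature deviation from the start temperature `ϑ0`:

```
μm(x4) = μm (1 + k_μ (x4 − ϑ0))      α(x4) = α (1 + k_α (x4 − ϑ0))
ẋ4 = (u(t) − x4) / T_θcs
```

This yields a compact non-autonomous model suitable for simulation and
for temperature-based control design. The nine constants
(μm, Pᵢ, Sm, Sᵢ, α, β, k_μ, k_α, T_θcs) are identified from dissolved-CO₂
measurements by minimising the integral absolute error (IAE) between
measured and simulated CO₂ with a bound-constrained particle swarm, in
two stages that mirror the two laboratory experiments:

1. **Stage 1** — a constant-temperature run (22 °C, ~24 h, 10-min
   sampling) identifies the six fundamental constants.
2. **Stage 2** — a run with a temperature step (22 → 27 °C at 3 h)
   identifies (k_μ, k_α, T_θcs) with the stage-1 constants frozen and ϑ0
   pinned to the start temperature.

The package is for bioprocess modellers and control engineers: it
provides the ODE models, a profile-aware simulator, a synthetic
measured-experiment generator with sensor noise and first-order
anti-noise filtering, a parameter-impact (sensitivity) analysis, the
staged PSO identification, and a statsmodels-style `FermentationModel` /
`FermentationResults` facade, plus a `fermkin` CLI.

## Worked example

```python
from fermkin import (FermentationModel, reference_constant_dataset,
                     reference_step_dataset)
from fermkin.datasets import REFERENCE_INIT

model = FermentationModel(
    reference_constant_dataset(),      # constant 22 °C, 24 h, 10-min sampling
    reference_step_dataset(3.0),       # 22 → 27 °C step at t = 3 h
    init=REFERENCE_INIT,               # measured loading: (2.6, 9.0, 0.1) mg/L
)
res = model.fit(seed=101)
print(res.summary())
```

prints

```
Two-stage PSO identification of the temperature-considered
batch-fermentation model (IAE objective, CO2 channel only)
==============================================================
parameter         estimate  unit
--------------------------------------------------------------
mu_m                2.1144  h^-1
p_i                 3.0306  g/L
s_m               0.030329  g/L
s_i                 7.3355  g/L
alpha              0.38002  g/L per g/L
beta              0.001999  h^-1
k_mu               0.14003  (degC)^-1
k_alpha           0.029985  (degC)^-1
t_theta_cs        0.099866  h
theta_0                 22  degC  (fixed)
--------------------------------------------------------------
stage 1: IAE 1.6212e-06 g*h/L in 219 iterations (132000 model evaluations)
stage 2: IAE 1.5321e-06 g*h/L in 67 iterations (10200 model evaluations)
seed: 101
```

The two datasets here are noiseless synthetic experiments generated from
the reference configuration (generating values μm = 2.1 h⁻¹, α = 0.38,
β = 0.002 h⁻¹, k_μ = 0.14 (°C)⁻¹, k_α = 0.03 (°C)⁻¹, T_θcs = 0.1 h), so
the fit should — and does — recover the identifiable constants: μm, α, β
and the three coupling parameters come back within ~1%. The inhibition
constants Pᵢ and Sᵢ wander (3.03 and 7.34 g/L against generating values
0.75 and 1.0) because the operating point keeps `x3 ≪ Pᵢ` and `x2 ≪ Sᵢ` —
the data carry almost no information about them (see `docs/methods.md`).
An IAE of ~1.6·10⁻⁶ g·h/L over 24 h means the fitted CO₂ curve tracks
the data to fractions of a percent of the ~4·10⁻³ g/L signal.

## Package layout

| module                | contents                                                    |
| --------------------- | ----------------------------------------------------------- |
| `fermkin.kinetics`    | parameter/state types, growth law, both model RHS           |
| `fermkin.simulate`    | temperature profiles, LSODA trajectory simulation           |
| `fermkin.identify`    | IAE objective, particle swarm, staged identification        |
| `fermkin.model`       | `FermentationModel` / `FermentationResults` facade          |
| `fermkin.sensitivity` | parameter sweeps, t90/final-CO₂ metrics, impact labels      |
| `fermkin.datasets`    | synthetic measured-experiment generator, reference fixtures |
| `fermkin.io`          | YAML config, CSV/JSON readers and writers                   |
| `fermkin.cli`         | `fermkin simulate / generate / identify* / sweep / classify`|
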