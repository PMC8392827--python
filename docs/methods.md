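# Methods

## Model

Batch milk fermentation is described by mass balances for microorganism
concentration `x1`, substrate `x2` and dissolved CO₂ `x3` (g/L). The
specific growth rate

φ(x2, x3) = μm · (1 − x3/Pᵢ) · x2 / (Sm + x2 + x2²/Sᵢ)

combines product inhibition, Monod saturation and substrate inhibition.
The fundamental model is ẋ1 = φ·x1, ẋ2 = −φ·x1, ẋ3 = (α·φ + β)·x1: growth
consumes substrate one-for-one (so x1 + x2 is conserved), and CO₂ is
produced both growth-associated (α) and growth-independent (β). The
inhibition factor (1 − x3/Pᵢ) is deliberately not floored at zero: past
x3 = Pᵢ the growth term goes negative, which represents the dying phase.

The temperature-considered model adds the bioreactor temperature `x4`
(°C), relaxing toward the heating-system reference u(t) with first-order
time constant T_θcs, and replaces μm and α by linear functions of the
temperature deviation from the start temperature ϑ0:

μm(x4) = μm·(1 + k_μ·(x4 − ϑ0)),  α(x4) = α·(1 + k_α·(x4 − ϑ0)).

A linear law suffices because fermentation temperatures move in a narrow
window (a few °C); both temperature-dependent factors multiply inside the
product balance, exactly as the state equations are posed. If either
adjusted parameter is driven non-positive the linearisation has left its
validity range and the simulation raises an error rather than clamping —
silent clamping would flatten the identification objective exactly where
the optimizer needs gradient information. ϑ0 is taken equal to the
initial content temperature x4(0).

### Units

The canonical internal concentration unit is g/L. The reference initial
loading is measured in mg/L — (2.6, 9.0, 0.1) mg/L — and converted on
input to (0.0026, 0.009, 0.0001) g/L. This reading is self-consistent:
the simulated CO₂ then stays inside the measuring electrode's linear
range (5·10⁻⁴–2·10⁻² g/L), and the operating point keeps x3 ≪ Pᵢ and
x2 ≪ Sᵢ, which is what makes the inhibition constants nearly inert (see
*Sensitivity* below).

### Reference configuration

| parameter | value | unit | role |
| --- | --- | --- | --- |
| μm | 2.1 | h⁻¹ | maximum specific growth rate |
| Pᵢ | 0.75 | g/L | product inhibition constant |
| Sm | 0.03 | g/L | substrate saturation constant |
| Sᵢ | 1.0 | g/L | substrate inhibition constant |
| α | 0.38 | – | growth-associated CO₂ yield |
| β | 0.002 | h⁻¹ | growth-independent CO₂ formation |
| k_μ | 0.14 | (°C)⁻¹ | temperature gain on μm |
| k_α | 0.03 | (°C)⁻¹ | temperature gain on α |
| T_θcs | 0.1 | h | heating-system lag (≈ 6 min) |
| ϑ0 | 22 | °C | start temperature |

## Simulation

Temperature protocols are piecewise-constant and right-continuous
(constant runs, and steps such as 22 → 27 °C at t = 3 h or 6 h).
Integration uses LSODA (via `scipy.integrate.odeint`, whose thin wrapper
matters because identification integrates the model tens of thousands of
times) with rtol 1e-8, atol 1e-10, restarted at every protocol breakpoint
so the discontinuity in u(t) is resolved exactly rather than smoothed by
the step controller. Default horizon 24 h; default output grid the 10-min
sensor sampling. Negative concentrations are monitored, not projected: a
state below −100·atol aborts. Halving the tolerances moves x3(24 h) by
< 10⁻¹¹ g/L on the reference run, and x1 + x2 drifts by < 10⁻⁹ g/L.

## Synthetic experiments

The generator emulates the laboratory measurement chain: simulate the
4-state model under a protocol, sample x3 every 10 min, optionally add
i.i.d. Gaussian sensor noise (default, when enabled without a magnitude:
2% of the noiseless signal range — the instrument noise level is not
documented, and 2% of range is a realistic figure for an ion-selective
electrode after analog filtering), optionally pass the noisy series
through a discrete first-order low-pass filter (zero-order-hold
discretisation), mirroring the analog anti-noise filter of the
acquisition hardware; the default leaves the filter off because the
hardware applies it before the data ever reach software. The generating
truth (parameters, seed, noise settings) travels in the dataset metadata.
The electrode's temperature-dependent calibration drift (~1.7% per 5 °C)
is a measurement-calibration behaviour, not fermentation dynamics, and is
not modelled.

What passing tests on these data do *not* show: real measured CO₂
carries drift, quantisation and temperature-dependent electrode slope
that the generator omits, so recovery results here bound what the
procedure can do under ideal sensing, not under all laboratory
conditions.

## Identification

The objective is the integral absolute error (IAE, trapezoidal) between
measured and simulated CO₂ on the sample grid; only the CO₂ channel is
fitted — the measured temperature channel is deliberately not part of the
objective. Initial concentrations are treated as known (they are
measured), not identified.

The optimizer is a global-best particle swarm with adaptive inertia in
[0.1, 1.1] (doubled while the swarm improves, halved after repeated
stalls), self/social acceleration 1.49, velocities clamped to the box
width, reflective bound handling, and stall-based stopping: terminate
when the best objective changes by less than 10⁻⁶ — relative to
max(1, |best|) — over a 20-iteration window, or at 500 iterations.
Identification bounds are broad and not centred on the truth:
μm ∈ [0.1, 10] h⁻¹, Pᵢ ∈ [0.01, 5], Sm ∈ [10⁻⁴, 1], Sᵢ ∈ [0.01, 10] g/L,
α ∈ [0.01, 2], β ∈ [10⁻⁵, 0.1] h⁻¹; k_μ ∈ [0, 1], k_α ∈ [0, 0.5] (°C)⁻¹,
T_θcs ∈ [0.01, 1] h.

Identification is staged: stage 1 fits the six fundamental constants on
a constant-temperature experiment (where the temperature extension is
inert); stage 2 fits (k_μ, k_α, T_θcs) on a step experiment with the
stage-1 constants frozen and ϑ0 pinned to the start temperature — the
coupling is structurally unidentifiable from a constant-temperature run,
so stage 2 rejects one.

### Swarm size and the ridge structure of the objective

The IAE surface is nearly degenerate along curved parameter ridges, a
classic case of kinetic-model sloppiness:

* because x2 < Sm along most of the trajectory, μm trades off against Sm
  (φ ≈ μm·x2/Sm), and an in-bounds ridge with Pᵢ pinned at its upper
  bound reaches IAE ≈ 2.5·10⁻⁵ g·h/L at μm ≈ 2× truth;
* a second branch with small Pᵢ (strong product inhibition mimicking a
  smaller growth rate) reaches IAE ≈ 2·10⁻⁶ at μm 20–45% below truth;
* in stage 2, a large heating lag (T_θcs ≈ 1 h) with inflated gains
  imitates the smoothed step response at IAE ≈ 1.3·10⁻⁴.

Only the true basin reaches IAE → 0 (the data are noiseless and the
fitter shares the generator's integrator), but a swarm that has collapsed
onto a ridge stalls there with a visually perfect fit and badly biased
parameters. Small swarms (10× dimension) land on a ridge on most seeds;
measured recovery of μm within 5% jumps from ~1/7 seeds at swarm 60 to
6/7 at swarm 600. The defaults are therefore 600 particles for the
6-parameter stage and 150 for the 3-parameter stage — diversity is the
cheap, honest cure here, and a stage-1 run still takes well under a
minute. α is insensitive to all of this (recovered to ~0.1% on
essentially every run): it is pinned by the total CO₂ rise, which no
ridge can imitate.

Consequence of the noiseless study conditions: the stall criterion keeps
registering > 10⁻⁶ improvements while the swarm polishes the degenerate
valley, so runs terminate after ~100–250 (stage 1) / ~50–120 (stage 2)
iterations. On real, noisy data the objective bottoms out at the sensor-
noise floor (~10⁻³ g·h/L for 2%-of-range noise) and the same rule stops
in a few dozen iterations. Iteration counts measured on noiseless
synthetic data are therefore *not* comparable to counts observed on
laboratory data with the same stopping rule.

Sensor noise changes the picture qualitatively. With 2%-of-range noise
the IAE bottoms out at its noise floor (≈ 1.5·10⁻³ g·h/L), two orders of
magnitude above the ridge-depth differences that pin μm on clean data:
every point of the ridge then fits equally well, the swarm stalls
wherever it happens to sit, and the recovered μm scatters across the
ridge (errors of 10–300% are typical) while the fitted CO₂ curve remains
indistinguishable from the data. α still comes back within ~1% — it is
identified by the total CO₂ rise, which noise cannot disguise. In
practice this means: from a single constant-temperature CO₂ experiment,
treat α (and, via stage 2, k_μ, k_α) as measured constants, but treat μm,
Pᵢ, Sm, Sᵢ and T_θcs as effective, dataset-specific values — perturbing
Pᵢ or Sᵢ by ±50% moves the objective by < 5% of what the same relative μm
perturbation does.

## Sensitivity analysis

Each of the six fundamental constants is swept (default grid 0.5×–2× of
base) and classified by its effect on two response metrics: the
steady-state metric is x3 at 24 h; the transient metric is the rise time
of the CO₂ curve. `response_metrics` reports t90 (time to 90% of the
total rise, linearly interpolated) by default, but the classification
uses the *half-rise* time: at the reference operating point the last
~13% of the 24-h rise is the slow β-creep (β·x1·t after substrate
exhaustion), so a 90% threshold lands in the creep tail and would
misattribute transient impact to the yield parameters α and β rather
than to the growth kinetics.

Sensitivity is the symmetric two-sided elasticity |Δm/m| / |Δp/p| at
±20%, averaged over the two sides; labels: significant ≥ 0.3, small in
[0.05, 0.3), very small < 0.05. On the reference configuration this
gives: μm the largest transient impact (elasticity ≈ 1.0) with
negligible steady-state impact; α the largest steady-state impact
(≈ 0.85) with modest transient impact; Pᵢ and Sᵢ negligible on both
(≈ 10⁻³); β a small steady-state contributor (≈ 0.13). One caveat the
numbers force on the verbal taxonomy: Sm's *transient* elasticity
(≈ 0.8) is genuinely large at this operating point — an unavoidable
consequence of x2 ≪ Sm — even though its steady-state impact is
negligible; the ranking of the top transient (μm) and top steady-state
(α) parameters is robust across perturbation sizes 10–30%.

## Numerical and design choices

* dx2 is computed as the exact negation of dx1, so x1 + x2 conservation
  holds bitwise at the RHS level and to solver tolerance along
  trajectories.
* Profiles are right-continuous; a step at t = 0 or with equal
  temperatures degenerates to a constant profile.
* The trapezoidal IAE is exact for piecewise-linear error curves, which
  anchors the closed-form oracle tests.
* PSO failure handling: objective exceptions and non-finite returns count
  as +∞; if more than half of all evaluations are non-finite the run
  aborts (the box is then mostly invalid and any "best point" would be
  meaningless).
* Problem sizes in the test suite and the acceptance script: 5 seeded
  stage-1 runs, 5 seeded stage-2 runs, 5 noisy stage-1 runs and one
  combined two-stage run, each on the 145-sample reference grid — enough
  to take medians over seeds while keeping a full run in minutes.

## Known limitations

* The temperature laws are linear in (x4 − ϑ0); far from ϑ0 they go
  invalid (negative rates) and the model refuses to extrapolate there.
* The identification treats the heating lag T_θcs as identifiable from
  CO₂ alone; it is only weakly so (a 6-min lag against multi-hour
  kinetics), which is why its acceptance band is ±50% and why the
  measured temperature channel, when available, is the better source.
* No uncertainty quantification: the staged PSO returns point estimates;
  the ridge analysis above is the qualitative substitute for confidence
  regions.
* pH, biomass viability phases and stirring effects are outside the
  model's state space.
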