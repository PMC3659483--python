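# Methods

## The generic cell model

`ionfit` simulates a single cardiac myocyte as a capacitive membrane
carrying a user-defined number N of time-dependent ionic currents plus a
time-independent leak:

    dEm/dt = -(i_stim + i_L + Σ_j i_j) / Cm
    i_j    = ḡ_j p_j q_j (Em − Erev,j)
    i_L    = ḡ_L (Em − Erev,L)

Each current is gated by two first-order Hodgkin–Huxley gates,

    dp/dt = α_p (1 − p) − β_p p        (likewise for q),

and every opening/closing rate is a three-parameter sigmoid of membrane
potential,

    rate(Em) = k / (1 + exp(s (Em − E50))),

with E50 shared between the α/β pair of a gate. A model with N currents
therefore has 2N + 1 state variables and 12N + 2 free parameters (twelve
per current — ḡ, Erev, and five per gate with the shared E50 counted
once — plus the leak conductance and reversal). Cm is treated as a fixed
property of the preparation, not a fitted parameter.

Assumptions worth stating explicitly:

- No intracellular calcium cycling, ion-concentration dynamics, pumps or
  exchangers: every mechanism must be absorbed into the voltage
  dependence of the generic currents. This is adequate for reproducing
  AP waveforms; it is not a mechanistic channel model.
- Gates appear to the first power only. Higher-order (e.g. n⁴) kinetics
  are representable as sums of two-gate currents (demonstrated by the
  voltage-clamp refits below), so powers are unnecessary for waveform
  fitting.
- The two gates of a current are structurally interchangeable, as are
  any two currents: fitted parameters are therefore not unique. The
  package treats waveforms and reconstructed current time courses, not
  parameter values, as the identifiable objects.

### Units and numerical choices

Internal units: time s, potential mV, rates s⁻¹, slopes mV⁻¹,
conductances µS/cm², Cm µF/cm², currents nA/cm². With these, dEm/dt in
mV/s needs no hidden conversion factor. User-facing durations quoted in
ms (pulse widths, pacing intervals) are converted at the interface.

- **Cm** defaults to 1 µF/cm² — the standard specific membrane
  capacitance; it also makes a 30 µA/cm² × 2 ms stimulus displace the
  membrane by ~60 mV, which is the right order for triggering atrial
  APs. Configurable on every model file.
- **Exponent clamping**: the sigmoid exponent s(Em − E50) is clamped to
  ±500 before `exp`, so rates saturate to 0 or k instead of overflowing
  when the optimiser probes extreme slopes.
- **Integrator**: `scipy.integrate.solve_ivp` with LSODA (stiff-capable;
  rate constants reach 5000 s⁻¹), rtol 1e-6 / atol 1e-8. The integration
  is restarted at every stimulus edge, because the rectangular applied
  current violates the smoothness assumption of adaptive steppers;
  within a segment the stimulus is constant. Tightening the tolerances
  tenfold moves simulated Em by well under 0.1 mV (tested).
- **Output grid**: 20 kHz by default, mirroring microelectrode
  acquisition; any explicit sample-time vector (e.g. recorded sample
  times) can be supplied instead.
- **State ordering** is fixed as (Em, p₁, q₁, …, p_N, q_N); gate values
  are clipped to [0, 1] on output (0 and 1 are invariant bounds of the
  gate ODE, so any excursion is solver noise).

### Feature extraction

AP cycles are delimited by upward crossings of dEm/dt > 500 mV/s
(first-order finite differences), debounced to one crossing per 50 ms.
The threshold separates the pacemaker depolarisation (tens of mV/s) from
the upstroke (≥ 1000 mV/s) in SAN traces; both values are configurable.
An initial transient — 1 s for spontaneous runs, the first pacing cycle
for paced ones — is excluded before computing periodic features. Per
cycle the package reports cycle length, maximum diastolic potential,
overshoot, maximum upstroke velocity, APD90 (NaN when the next stimulus
interrupts repolarisation) and the peak magnitude max|i_j(t)| of each
current. "Mean peak" quantities average over all complete post-transient
cycles; the number of cycles averaged is therefore set by the simulated
duration, which is a caller choice (the shipped workflows use 5 s with
1 s discarded, i.e. ~10 cycles of a ~400 ms rhythm).

## The curvilinear-gradient optimiser

Fitting minimises Q = rᵀr where r stacks weighted residuals
(model − data, times √weight) over all samples and datasets. Each
iteration builds the local quadratic model Q₀ + ΔpᵀG + ½ΔpᵀHΔp with
G = 2Jᵀr₀ and H = 2JᵀJ from a forward finite-difference Jacobian, then
searches the **true** objective along the steepest-descent curve of that
quadratic,

    L(a) = (exp(−Ha) − I) H⁻¹ G,    a ∈ [0, ∞),

whose tangent at a = 0 is −G (gradient descent) and whose a → ∞ limit is
the Newton step −H⁻¹G. The curve is evaluated through the
eigendecomposition of H; the coefficient (e^{−λa} − 1)/λ has the finite
limit −a as λ → 0, so singular Hessians need no regularisation on the
path (the explicit Newton endpoint uses an eigenvalue floor of
1e-10·λmax). The line search samples a log grid of a spanning
1e-3/λmax to 1e3/λmin plus the Newton endpoint, then refines the best
bracket by bounded scalar minimisation in log a. A step is accepted only
if the true objective decreases, so the per-iteration objective history
is non-increasing by construction; iteration stops when the relative
decrease falls below `tol` (default 1e-8) or `max_iterations` is hit.

Supporting choices:

- **Finite differences**, relative step 1e-4 with an absolute floor of
  1e-8, probing backwards at bound edges or when a probe returns
  non-finite residuals. FD keeps the residual contract black-box (any
  callable works — ODE fits and closed-form clamp fits share the same
  optimiser); sensitivity ODEs would be faster but model-specific.
- **Scaling**: parameters are optimised as p/scale with scale =
  max(|p₀|, 1), since conductances (10⁴) and slopes (10⁻¹) span five
  orders of magnitude.
- **Bounds** by projection: k ∈ [0, 5000] s⁻¹, ḡ ∈ [0, 4×10⁴] µS/cm²,
  |s| ≤ 5 mV⁻¹, potentials in [−100, 100] mV. The caps mirror where
  fitted values pile up in practice (many optimised rates sit at
  4999–5000 s⁻¹, conductances just below 4×10⁴); without such asymmetric
  caps the interchange symmetries above make the search space needlessly
  redundant.
- **Random restarts** (off by default) draw uniformly within the bounds
  from an explicit seed; the best run wins. **Iterative reweighting**
  (weights ∝ 1/(|r| + ε), refreshed every R accepted iterations) is
  implemented but off by default, because it changes the objective being
  minimised and its exact schedule is a matter of taste; the final
  reported objective is always unweighted-by-IRLS.
- A simulation failure at a probe point becomes a +∞ residual, so the
  line search simply rejects that point instead of aborting the fit.

## Multi-dataset fitting

R datasets are fitted jointly by concatenating their weighted residuals.
Three sharing schemes set the global parameter layout: **shared** (n
parameters), **independent** (nR), and **mixed** — S named parameters
take a per-dataset value, giving n + (R − 1)·S globals (the base block
serves dataset 0; each further dataset appends its S-vector). The mixed
scheme expresses drug-block fits (one conductance differs between
control and drug) and tissue-heterogeneity fits (all conductances
differ, kinetics shared). The stacked Jacobian inherits the obvious
block sparsity, which is verified by finite differences in the tests.

Per-dataset initial states are fixed inputs by default: recordings come
with their own initial conditions, and freeing 2N + 1 extra states per
dataset worsens identifiability. Setting `fit_initial_states=True` on a
`MultiFitProblem` appends each dataset's state (Em in [−100, 100] mV,
gates in [0, 1]) to the global vector as data-specific free parameters
for cases where the starting conditions are genuinely unknown. Datasets are not re-weighted relative to
one another — each contributes in proportion to its sample count —
because any such weighting is a modelling decision the caller should
make through the per-sample weights. Stimulus-artifact windows default
to [onset, onset + width + 1 ms] with weight zero.

## Synthetic data

The generator emulates sharp-microelectrode AP recordings: a known model
is simulated at 20 kHz, additive noise is drawn (uniform by default,
since recording noise is usually quoted as a ± band; gaussian optional)
and rescaled so the empirical peak-to-peak equals the requested level
(default ±0.96 mV, i.e. 1.92 mV full swing, RMS ≈ 0.554 mV), and —
optionally — square artifact deflections are injected during stimulus
pulses with a matching zero-weight mask. Random pacing sequences draw
100 intervals from Normal(275 ms, 69 ms), truncated below at 120 ms
(≈ 2.25 SD below the mean, so truncation is negligible while excluding
unphysiologically early pulses). The generating parameters travel with
each dataset for recovery tests.

What the generator does **not** emulate: electrode drift, junction
potentials, filtering artifacts, cell-to-cell coupling, or any model
mismatch — the data-generating family is the fitting family. Passing
recovery tests therefore demonstrates that the optimiser can invert the
forward map under realistic noise, not that the model family fits real
myocytes; the fixture models (fitted to real SAN/atrial recordings)
cover the latter qualitatively.

### Voltage-clamp reference

For checking that first-order two-gate kinetics can mimic higher-order
gating, the package ships the classic squid-axon iK (gK n⁴, 36 mS/cm²,
EK −77 mV) and iNa (gNa m³h, 120 mS/cm², ENa +50 mV) at the original
6.3 °C rate constants in the modern sign convention (constants tabulated
in `ionfit/hh.py`). Under a voltage step all gates relax in closed form,
so clamp fitting requires no ODE solver. The clamp-fit start heuristic
assigns each generic current an activating p gate with time constants
staggered logarithmically across the trace, a near-sustained q gate, a
reversal potential placed on the far side of the test potential so the
current can carry the target's sign, and conductances sized from the
target peak; the fit is repeated from several independently jittered
such starts, and the winner is polished with progressively finer
finite-difference steps (1e-6 then 1e-7 relative), which releases the
shallow plateaus the default 1e-4 step cannot resolve in this
deliberately redundant parameterisation.

## Problem sizes in the shipped workflows

The bundled reproduction workflows (`ionfit.experiments`, also run by
`scripts/acceptance.py`) use: 5 s spontaneous simulations with 1 s
discarded for current-reconstruction measurements; 50 × 100 intervals
for pacing statistics; a 1 s cSAN recording fitted on a 2 kHz decimation
of the 20 kHz trace (m = 2001, n = 26) with RMS reported on the full
grid, started from a seeded ±20% perturbation of all parameters; and
clamp refits on 1501 (iK) / 801 (iNa) samples. These sizes keep the full
set in the minutes range on one core while leaving each measurement
comfortably resolved.

## Known limitations

- Parameters are not identifiable (interchange symmetries, plateaued
  rates at bounds); only waveforms and current time courses are.
- The optimiser is local; restarts mitigate but do not remove
  sensitivity to the starting point, and joint fits with shared
  parameters have visibly rougher objective surfaces than single fits.
- Spontaneous-model fitting is phase-sensitive: long records with a
  slightly wrong cycle length produce large residuals, so recovery
  workflows fit one to two cycles.
- No automatic selection of N: currents are added manually when the
  target RMS cannot be reached, and similar currents can be merged by
  the user after inspection.
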