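# ionfit

Generic N-current cardiomyocyte models and curvilinear-gradient
least-squares fitting of action-potential recordings.

## The problem

Biophysically detailed cardiac cell models are expensive and hard to
parameterise; two-variable phenomenological models cannot reproduce AP
morphology changes under drugs or varied pacing. `ionfit` implements the
intermediate approach: a Hodgkin–Huxley-type cell with a **user-defined
number N of identical two-gate currents**,

    dEm/dt = -(i_stim + i_L + Σ_j ḡ_j p_j q_j (Em − Erev,j)) / Cm,
    dp/dt  = α_p (1 − p) − β_p p,      α, β = k / (1 + exp(s (Em − E50))),

giving 2N+1 state variables and 12N+2 free parameters, all of which are
estimated directly from recorded membrane-potential traces. Parameter
estimation uses a curvilinear-gradient least-squares method that
searches the true objective along the steepest-descent curve of the
local quadratic model,

    L(a) = (e^{−Ha} − I) H⁻¹ G,    G = 2 Jᵀ r,  H = 2 Jᵀ J,

interpolating continuously between gradient descent (a → 0) and the
Newton step (a → ∞). Several recordings — different pacing protocols,
drug conditions, or cell types — can be fitted simultaneously with
**shared**, **independent**, or **mixed** parameter-sharing schemes
(e.g. one drug-sensitive conductance per condition, everything else
shared), which is what constrains the reconstructed ionic current time
courses to be physiologically meaningful.

The package is for cellular electrophysiologists and modellers who want
compact AP models fitted to their own microelectrode recordings, and it
ships ready-made fitted models for rabbit central/peripheral sinoatrial
node and atrial myocytes as fixtures.

## Worked example

Simulate the bundled four-current peripheral-SAN model under control
conditions and with the rapid delayed-rectifier current (i3 ≡ iKr)
partially blocked by E-4031 — the two conditions share every parameter
except the i3 maximum conductance:

```python
import numpy as np
import ionfit

for cond in ("control", "e4031"):
    params, x0 = ionfit.io.drug_model(cond)
    trace = ionfit.simulate(params, x0, ionfit.StimulusProtocol.spontaneous(),
                            5.0, record_currents=True)
    feats = ionfit.extract_features(trace, discard=1.0)
    print(f"{cond:8s}: peak |i3| = {feats.mean_current_peak(3)/1e3:6.2f} uA/cm2, "
          f"APD90 = {np.nanmean(feats.apd90)*1e3:5.0f} ms, "
          f"MDP = {feats.max_diastolic_potential.mean():6.1f} mV")
```

prints

```
control : peak |i3| =  18.75 uA/cm2, APD90 =   142 ms, MDP =  -76.9 mV
e4031   : peak |i3| =  12.79 uA/cm2, APD90 =   227 ms, MDP =  -66.3 mV
```

Reducing the single drug-sensitive conductance (2438 → 1562 µS/cm²)
shrinks the reconstructed iKr peak by a third, prolongs the action
potential by ~85 ms and depolarises the maximum diastolic potential by
~10 mV — the classic electrophysiological signature of iKr block,
emerging from the fitted generic model rather than being imposed.

The `examples/` directory holds one short script per capability:
spontaneous pacemaker simulation, drug block, random pacing, noisy
parameter recovery, fitting generic currents to Hodgkin–Huxley n⁴/m³h
voltage-clamp steps, and mixed-scheme multi-dataset fitting. A thin CLI
(`ionfit simulate|fit|generate|surface`) wraps the same library calls
for shell use; `docs/methods.md` documents the model, the optimiser and
all numerical choices.

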