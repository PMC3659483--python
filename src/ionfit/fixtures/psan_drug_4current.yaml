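model:
  N: 4
  Cm: 1.0
  leak: {g: 13.58, Erev: -99.56}
  currents:
  - g: 97
    Erev: -55.54
    p: {k_a: 4988.66, s_a: -0.084, k_b: 2383.24, s_b: 0.19, E50: -89.62}
    q: {k_a: 587.81, s_a: -0.1, k_b: 4049.79, s_b: 0.019, E50: -84.76}
  - g: 127.61
    Erev: -97.79
    p: {k_a: 3178.26, s_a: -0.0068, k_b: 4828.39, s_b: 0.0017, E50: 16.61}
    q: {k_a: 85.64, s_a: -1.5e-05, k_b: 920.57, s_b: 0.184, E50: -17.22}
  - g: 2438.4
    Erev: -79.96
    p: {k_a: 3128, s_a: -0.2, k_b: 72.52, s_b: 0.0114, E50: 9.81}
    q: {k_a: 162.53, s_a: 0.0254, k_b: 185.48, s_b: -0.14, E50: -99.92}
  - g: 12279.67
    Erev: 43.39
    p: {k_a: 2545.56, s_a: -0.09386, k_b: 1965.64, s_b: 0.00024, E50: 7.38}
    q: {k_a: 0.83, s_a: 0.2, k_b: 12.01, s_b: -0.0007, E50: -22.4}
g3: {control: 2438.4, e4031: 1562.28}
initial_states:
  control:
    Em: -76.9
    gates: [0.94, 0.17, 0.37, 0.03, 0.04, 0.22, 0, 0.08]
  e4031:
    Em: -68.1
    gates: [0.98, 0.14, 0.37, 0, 0, 0.03, 0.004, 0.085]
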