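cells:
  cSAN:
    model:
      N: 2
      Cm: 1.0
      leak: {g: 3.7, Erev: -42.59}
      currents:
      - g: 95.71
        Erev: -91.74
        p: {k_a: 4932.74, s_a: -1.84, k_b: 15.26, s_b: 2.48, E50: -30.44}
        q: {k_a: 1.4, s_a: -3.86, k_b: 7.92, s_b: 0.1, E50: -36.17}
      - g: 17722.1
        Erev: 11.38
        p: {k_a: 0.44, s_a: -4.98, k_b: 3851.95, s_b: 0.26, E50: -47.98}
        q: {k_a: 4.36, s_a: 3.51, k_b: 43.47, s_b: -4.47, E50: -36.24}
    initial_state:
      Em: -55.65
      gates: [0.23, 0.07, 0.0, 0.47]
  pSAN:
    model:
      N: 2
      Cm: 1.0
      leak: {g: 4.0, Erev: -69.32}
      currents:
      - g: 60.29
        Erev: -92.8
        p: {k_a: 4990.73, s_a: -2.92, k_b: 41.15, s_b: 5.0, E50: -62.41}
        q: {k_a: 6.61, s_a: -2.09, k_b: 7.81, s_b: 0.92, E50: -53.46}
      - g: 17966.7
        Erev: 6.98
        p: {k_a: 2.8, s_a: -4.99, k_b: 4612.17, s_b: 0.7, E50: -70.14}
        q: {k_a: 9.95, s_a: 3.04, k_b: 62.65, s_b: -4.67, E50: -69.46}
    initial_state:
      Em: -74.09
      gates: [0.063, 0.28, 0.0, 0.38]
  RA:
    model:
      N: 2
      Cm: 1.0
      leak: {g: 1.74, Erev: -58.98}
      currents:
      - g: 33.55
        Erev: -97.71
        p: {k_a: 3099.16, s_a: -0.1, k_b: 4477.72, s_b: 0.15, E50: -77.65}
        q: {k_a: 170.9, s_a: -0.01, k_b: 0.01, s_b: 0.19, E50: -80.46}
      - g: 9962.91
        Erev: 14.54
        p: {k_a: 300.89, s_a: -0.2, k_b: 4030.31, s_b: 0.02, E50: -51.73}
        q: {k_a: 16.86, s_a: 0.2, k_b: 52.61, s_b: -0.18, E50: -75.74}
    initial_state:
      Em: -81.35
      gates: [0.79, 0.39, 0.0, 0.3]
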