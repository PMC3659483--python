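model:
  N: 7
  Cm: 1.0
  leak: {g: 12.96, Erev: -82.72}
  currents:
  - g: 3791.62
    Erev: -99.82
    p: {k_a: 4680.75, s_a: -0.074, k_b: 1577.04, s_b: 0.17, E50: -99.9}
    q: {k_a: 8.78, s_a: 0, k_b: 4976.46, s_b: 0, E50: -67.02}
  - g: 1112.87
    Erev: -90.46
    p: {k_a: 2452.15, s_a: -0.19, k_b: 17.13, s_b: 0.036, E50: 22.84}
    q: {k_a: 133.46, s_a: 0.0012, k_b: 1285.7, s_b: -0.11, E50: -94.5}
  - g: 24.99
    Erev: -60.73
    p: {k_a: 4309.86, s_a: -0.16, k_b: 1882.61, s_b: 0, E50: 14.65}
    q: {k_a: 201.88, s_a: 0.19, k_b: 0.0037, s_b: -0.031, E50: -21.182}
  - g: 334.03
    Erev: -27.89
    p: {k_a: 1351.75, s_a: -0.2, k_b: 97.24, s_b: 0.00021, E50: -64.5}
    q: {k_a: 1342.22, s_a: 0.2, k_b: 2100.13, s_b: -0.16, E50: -100}
  - g: 5211.15
    Erev: 53.14
    p: {k_a: 20.51, s_a: -0.084, k_b: 1035.9, s_b: 0.00018, E50: 7.32}
    q: {k_a: 967.19, s_a: 0.2, k_b: 145.5, s_b: -0.034, E50: 0.32}
  - g: 615.19
    Erev: 30.14
    p: {k_a: 3406.11, s_a: -0.19, k_b: 4991.79, s_b: 0.074, E50: -43.38}
    q: {k_a: 230.35, s_a: 0.17, k_b: 19.01, s_b: -0.19, E50: -100}
  - g: 39984.07
    Erev: 73.64
    p: {k_a: 1547.59, s_a: -0.19, k_b: 4097.16, s_b: 0.15, E50: -72.4}
    q: {k_a: 4.5, s_a: 0.19, k_b: 1159.7, s_b: -0.19, E50: -99.88}
initial_states:
  PI400:
    Em: -78.79
    gates: [0.99, 0.004, 8.0e-06, 0.043, 0, 1, 0.82, 0.0094, 9.0e-05, 0.98, 0.00056,
      0.32, 0.18, 0.00035]
  PI200:
    Em: -77.96
    gates: [0.99, 0.0014, 0.13, 0.074, 0, 1, 0.74, 0.0073, 3.1e-05, 0.99, 0.00094,
      0.1, 0.17, 9.5e-05]
  random:
    Em: -77.96
    gates: [0.99, 0.0014, 0.13, 0.074, 0, 1, 0.74, 0.0073, 3.1e-05, 0.99, 0.00094,
      0.1, 0.17, 9.5e-05]
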