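model:
  N: 7
  Cm: 1.0
  leak: {g: 10.08, Erev: -91.4}
  currents:
  - g: 1577.21
    Erev: -99.65
    p: {k_a: 4843.48, s_a: -0.0909, k_b: 2227.67, s_b: 0.175, E50: -96.1}
    q: {k_a: 19.74, s_a: -0.00423, k_b: 4974.17, s_b: 0.000113, E50: -42.6}
  - g: 1154.71
    Erev: -97.08
    p: {k_a: 2636.7, s_a: -0.168, k_b: 18.19, s_b: 0.0265, E50: -1.19}
    q: {k_a: 19.48, s_a: 0.0026, k_b: 1236.21, s_b: -0.117, E50: -98.56}
  - g: 24.99
    Erev: -60.94
    p: {k_a: 4265.53, s_a: -0.131, k_b: 1505.24, s_b: 0.000276, E50: 23.46}
    q: {k_a: 357.63, s_a: 0.198, k_b: 209.24, s_b: -0.0255, E50: -36.83}
  - g: 1014.53
    Erev: -29.09
    p: {k_a: 1197.1, s_a: -0.199, k_b: 138.93, s_b: 0.00021, E50: -61.64}
    q: {k_a: 1068.0, s_a: 0.2, k_b: 2699.34, s_b: -0.177, E50: -100.0}
  - g: 2469.15
    Erev: 63.89
    p: {k_a: 25.37, s_a: -0.0854, k_b: 1448.56, s_b: 7.27e-05, E50: -0.127}
    q: {k_a: 1118.86, s_a: 0.2, k_b: 303.27, s_b: -0.0199, E50: -4.22}
  - g: 1376.76
    Erev: 30.66
    p: {k_a: 3472.1, s_a: -0.1805, k_b: 4999.96, s_b: 0.0852, E50: -43.024}
    q: {k_a: 620.38, s_a: 0.1847, k_b: 64.29, s_b: -0.187, E50: -83.15}
  - g: 15.83
    Erev: 80.96
    p: {k_a: 2083.24, s_a: -0.196, k_b: 4601.0, s_b: 0.158, E50: -56.47}
    q: {k_a: 78.65, s_a: 0.195, k_b: 455.47, s_b: -0.181, E50: -92.11}
conductances:
  cSAN:
    g: [1577.21, 1154.71, 24.99, 1014.53, 2469.15, 1376.76, 15.83]
    gL: 10.08
  RA:
    g: [7526.58, 66.55, 76.99, 50.0, 2591.45, 370.33, 39997.86]
    gL: 0.043
initial_states:
  cSAN:
    Em: -69.08
    gates: [0.996, 0.0036, 0.208, 0.0088, 0, 0.847, 0.77, 0.0008, 0.0001, 0.946, 0.0068,
      0.398, 0.0366, 0.0021]
  RA:
    Em: -79.93
    gates: [0.97, 0.0035, 0.093, 0.009, 0, 0.87, 0.32, 0.0072, 3.2e-05, 0.95, 0.0009,
      0.84, 0.0047, 0.015]
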