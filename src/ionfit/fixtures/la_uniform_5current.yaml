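runs:
  run1:
    model:
      N: 5
      Cm: 1.0
      leak: {g: 107.47, Erev: -99.98}
      currents:
      - g: 3044.83
        Erev: 0.0005
        p: {k_a: 4483.62, s_a: -0.0921, k_b: 0.21, s_b: 0.196, E50: -28.97}
        q: {k_a: 1375.78, s_a: -0.2, k_b: 4761.23, s_b: 0.0032, E50: 21.57}
      - g: 42.24
        Erev: -80.0
        p: {k_a: 115.88, s_a: -0.136, k_b: 217.08, s_b: 0.2, E50: -65.89}
        q: {k_a: 1210.4, s_a: -0.2, k_b: 2603.48, s_b: 0.0004, E50: -99.87}
      - g: 7192.04
        Erev: 51.31
        p: {k_a: 64.45, s_a: -0.09, k_b: 4309.81, s_b: 0.0244, E50: -39.76}
        q: {k_a: 252.37, s_a: 0.0978, k_b: 8.01, s_b: -0.106, E50: -96.83}
      - g: 39997.9
        Erev: 72.48
        p: {k_a: 2392.17, s_a: -0.159, k_b: 4999.04, s_b: 0.173, E50: -48.04}
        q: {k_a: 46.66, s_a: 0.132, k_b: 1309.81, s_b: -0.18, E50: -73.25}
      - g: 3577.89
        Erev: 5.51
        p: {k_a: 1943.58, s_a: -0.199, k_b: 42.81, s_b: 0.0168, E50: 26.49}
        q: {k_a: 433.93, s_a: 0.0004, k_b: 1244.48, s_b: -0.176, E50: -98.74}
    initial_states:
      PI400:
        Em: -80.32
        gates: [0.99, 0, 0.07, 0.45, 0.0006, 0.87, 0.0027, 0.11, 0.004, 0.16]
      PI200:
        Em: -77.8
        gates: [0.99, 0, 0.9, 0.42, 0.0018, 0.64, 0.0069, 0.057, 0.0081, 0.035]
      PI300:
        Em: -80.4
        gates: [0.99, 0, 0.066, 0.45, 0.006, 0.87, 0.0026, 0.113, 0.0002, 0.16]
  run2:
    model:
      N: 5
      Cm: 1.0
      leak: {g: 123.02, Erev: -99.93}
      currents:
      - g: 1926.84
        Erev: 0.025
        p: {k_a: 4425.83, s_a: -0.0772, k_b: 11.6, s_b: 0.197, E50: -41.0}
        q: {k_a: 2117.98, s_a: -0.194, k_b: 3987.49, s_b: 0.0008, E50: 27.5}
      - g: 29.84
        Erev: -80.0
        p: {k_a: 19.19, s_a: -0.117, k_b: 164.94, s_b: 0.2, E50: -68.28}
        q: {k_a: 985.06, s_a: -0.193, k_b: 2516.13, s_b: 0.0115, E50: -97.95}
      - g: 4338.65
        Erev: 37.11
        p: {k_a: 129.11, s_a: -0.0941, k_b: 4587.86, s_b: 0.0361, E50: -39.2}
        q: {k_a: 439.94, s_a: 0.118, k_b: 8.38, s_b: -0.073, E50: -99.51}
      - g: 39857.1
        Erev: 62.36
        p: {k_a: 2330.46, s_a: -0.15, k_b: 4995.38, s_b: 0.189, E50: -48.21}
        q: {k_a: 48.78, s_a: 0.125, k_b: 1172.17, s_b: -0.186, E50: -74.12}
      - g: 4188.07
        Erev: 3.62
        p: {k_a: 1303.25, s_a: -0.2, k_b: 57.75, s_b: 0.0116, E50: 20.86}
        q: {k_a: 668.38, s_a: 0.0106, k_b: 884.84, s_b: -0.0946, E50: -92.4}
    initial_states:
      PI400:
        Em: -79.26
        gates: [0.95, 0, 0.027, 0.46, 0, 0.84, 0.0044, 0.089, 0, 0.31]
      PI200:
        Em: -77.8
        gates: [0.99, 0, 0.9, 0.42, 0.0018, 0.64, 0.0069, 0.057, 0.0081, 0.035]
      PI300:
        Em: -82.14
        gates: [0.52, 0, 0.045, 0.45, 0.0005, 0.93, 0.0029, 0.14, 0.0006, 0.27]
  run3:
    model:
      N: 5
      Cm: 1.0
      leak: {g: 92.5, Erev: -99.89}
      currents:
      - g: 4547.51
        Erev: 0.0954
        p: {k_a: 4619.86, s_a: -0.0516, k_b: 20.29, s_b: 0.199, E50: 9.25}
        q: {k_a: 1076.29, s_a: -0.196, k_b: 4844.62, s_b: 0.0028, E50: 15.69}
      - g: 66.49
        Erev: -80.14
        p: {k_a: 82.99, s_a: -0.132, k_b: 283.28, s_b: 0.2, E50: -60.91}
        q: {k_a: 1311.51, s_a: -0.2, k_b: 3055.08, s_b: 0.0012, E50: -71.0}
      - g: 3904.66
        Erev: 59.56
        p: {k_a: 79.2, s_a: -0.104, k_b: 4598.48, s_b: 0.0273, E50: -39.52}
        q: {k_a: 365.37, s_a: 0.1, k_b: 5.46, s_b: -0.176, E50: -95.5}
      - g: 38120.4
        Erev: 75.24
        p: {k_a: 1884.15, s_a: -0.161, k_b: 4938.09, s_b: 0.166, E50: -48.04}
        q: {k_a: 22.51, s_a: 0.124, k_b: 1677.5, s_b: -0.16, E50: -64.6}
      - g: 3353.9
        Erev: 7.54
        p: {k_a: 1115.88, s_a: -0.197, k_b: 38.07, s_b: 0.0133, E50: 30.38}
        q: {k_a: 497.48, s_a: 0.0015, k_b: 985.96, s_b: -0.0468, E50: -97.38}
    initial_states:
      PI400:
        Em: -79.86
        gates: [0.7, 0, 0.022, 0.11, 0.0003, 0.92, 0.0022, 0.126, 0.0002, 0.264]
      PI200:
        Em: -78.61
        gates: [0.72, 0, 0.027, 0.133, 0.0004, 0.883, 0.0027, 0.102, 0.0015, 0.26]
      PI300:
        Em: -79.96
        gates: [0.69, 0, 0.022, 0.109, 0.0003, 0.922, 0.0022, 0.128, 0.0001, 0.264]
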