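minimal_2current.yaml: {description: 'Two-current spontaneous/paced cell models for
    rabbit central SAN, peripheral SAN and right atrial myocytes, with their initial
    states.'}
la_uniform_5current.yaml:
  description: Five-current left-atrial model fitted simultaneously to uniform pacing
    at 400 and 200 ms intervals; three optimisation runs from randomised starts, each
    with initial states for pacing intervals 400/200/300 ms. Paced with 2 ms, 13 uA/cm2
    pulses.
  corrections:
  - {where: run2 i4 q s_beta, note: ambiguous printed value '-0.1.86' interpreted
      as -0.186}
la_random_7current.yaml: {description: 'Seven-current left-atrial model fitted to
    uniform (400, 200 ms) and randomly paced data; shared parameters, per-protocol
    initial states. Paced with 2 ms, 30 uA/cm2 pulses; random pacing intervals ~ Normal(275
    ms, 69 ms).'}
psan_drug_4current.yaml: {description: 'Four-current peripheral SAN model fitted jointly
    to control and E-4031 (iKr block) recordings; only the i3 maximum conductance
    differs between conditions (control 2438.40, E-4031 1562.28 uS/cm2). The shipped
    model carries the control value; use the g3 map and the matching initial state
    for the drug condition.'}
tissue_7current.yaml:
  description: Seven-current model fitted jointly to cSAN and RA recordings with shared
    kinetics; all eight maximum conductances (seven currents plus leak) are cell-specific.
    The shipped model carries the cSAN conductances; use the conductance map for RA.
    RA paced with 2 ms, 22 uA/cm2 pulses.
  corrections:
  - {where: i4 p s_alpha, note: ambiguous printed value '-0.1.99' interpreted as -0.199}
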