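{
  "name": "stdp",
  "kind": "fplr1d",
  "provenance": "Spike-timing-dependent plasticity parameter table (pairing of one presynaptic and one postsynaptic spike; rates deliberately small so that single pairings produce small weight changes)",
  "time_unit": "ms",
  "dt": 0.01,
  "thresholds": {"theta_D": 1.0, "theta_P": 1.3},
  "fixed_points": [1.0, 0.42, 2.25],
  "learning_rates": [0.0, 0.001, 0.00075],
  "calcium": {"C_pre": 0.9, "C_post": 1.55, "tau_Ca": 7.0},
  "w0": 1.0
}
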