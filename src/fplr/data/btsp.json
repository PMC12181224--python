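{
  "name": "btsp",
  "kind": "fplr1d",
  "provenance": "Behavioral-timescale plasticity parameter table (leaky-integrator place-field simulation with slow ER-dominated calcium decay)",
  "time_unit": "ms",
  "dt": 1.0,
  "thresholds": {"theta_D": 1.5, "theta_P": 2.15},
  "fixed_points": [0.2, 0.2, 2.5],
  "learning_rates": [0.0, 0.0017, 0.15],
  "w0": 0.2,
  "track": {"T": 10000.0, "N": 1000, "r": 400.0, "P_max": 0.02},
  "neuron": {
    "C_m": 1.0,
    "tau_V": 15.0,
    "V_rest": -75.0,
    "V_plateau": -30.0,
    "epsp_per_unit_weight": 0.4
  },
  "btsp_calcium": {
    "pre_height": 0.1,
    "plateau_height": 1.33,
    "plateau_duration": 300.0,
    "tau_Ca": 2000.0
  }
}
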