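{
  "name": "frequency",
  "kind": "fplr1d",
  "provenance": "Frequency-dependent plasticity parameter table (hippocampal early-phase calibration; F_D from in-vivo LFS-LTD at 42% of baseline, F_P from in-vitro HFS-LTP at 225% of baseline)",
  "time_unit": "ms",
  "dt": 0.01,
  "thresholds": {"theta_D": 1.0, "theta_P": 1.3},
  "fixed_points": [1.0, 0.42, 2.25],
  "learning_rates": [0.0, 0.04, 0.055],
  "calcium": {"C_pre": 1.05, "C_post": 0.0, "tau_Ca": 10.0},
  "w0": 1.0
}
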