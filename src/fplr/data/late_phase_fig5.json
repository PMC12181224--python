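{
  "name": "late_phase_fig5",
  "kind": "protein_gated",
  "provenance": "Protein-gated late-phase calibration: early LTD to 42% (9-s depressive calcium from 900 pulses x 10 ms at 1 Hz), early LTP to 225% (3-s potentiative calcium from 3 x 100 pulses x 10 ms at 100 Hz); hours-scale drift at the mean fitted rate 0.0046 per second; with protein, LTD stabilizes at 61% and LTP at 142% of baseline",
  "time_unit": "s",
  "dt": 1.0,
  "thresholds": {"theta_D": 1.0, "theta_P": 1.3},
  "no_protein": {
    "fixed_points": [1.0, 0.42, 2.25],
    "learning_rates": [0.0046, 1.0, 1.0]
  },
  "protein": {
    "depressive": {"F": 0.42, "eta": 1.0},
    "potentiative": {"F": 2.25, "eta": 1.0},
    "pre_depressive_basins": {
      "fixed_points": [0.61, 1.0, 1.42],
      "boundaries": [0.0, 0.8, 1.2, 2.5],
      "learning_rates": [0.0046, 0.0046, 0.0046]
    }
  },
  "protocol": {
    "ltd_hold_level": 1.15,
    "ltp_hold_level": 1.6,
    "ltd_early_duration_s": 9.0,
    "ltp_early_duration_s": 3.0,
    "ltd_late_duration_s": 16200.0,
    "ltp_late_duration_s": 36000.0
  },
  "w0": 1.0
}
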