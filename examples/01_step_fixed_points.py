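"""Probe the early-phase fixed points with the canonical step stimulus.

Holding calcium at a constant level inside one plasticity region drives
the synaptic weight asymptotically to that region's fixed point; the
asymptote is the fixed point by definition, independent of the exact held
level.  With the frequency preset a depressive hold lands at 42% of
baseline and a potentiative hold at 225%.
"""

from fplr import load_preset, run_step_protocol

preset = load_preset("frequency")
theta_D, theta_P = preset.thresholds.theta_D, preset.thresholds.theta_P

for label, level in (("depressive", (theta_D + theta_P) / 2),
                     ("potentiative", theta_P + 0.3)):
    res = run_step_protocol(level, duration_on=500.0, duration_off=1.0,
                            w0=1.0, preset=preset)
    print(f"{label:>13} hold at Ca={level:.2f}: "
          f"w 1.00 -> {res.weights.final:.4f} "
          f"({100 * res.weights.final:.1f}% of baseline)")

print("\nThe two asymptotes are the region fixed points F_D and F_P; the")
print("held calcium level only sets how fast they are reached, not where.")
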