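"""Protein-gated late-phase plasticity.

Early plasticity drives the weight to the early fixed point within
seconds (LTD: 42% of baseline after a 9-s depressive calcium signal;
LTP: 225% after 3 s of potentiative calcium).  Over the following hours
the weight drifts at 0.0046 per second: back to baseline if protein
synthesis is blocked, or into a stabilized basin (61% for LTD, 142% for
LTP) if the stabilizing protein is present.
"""

from fplr import run_late_phase_experiment

for direction in ("ltd", "ltp"):
    for protein in (True, False):
        res = run_late_phase_experiment(direction, protein=protein)
        tag = "protein " if protein else "no protein"
        print(f"{direction.upper()} ({tag}): early -> "
          f"{100 * res.summary['w_after_early']:.0f}% of baseline, "
          f"after {res.summary['late_duration_s'] / 3600:.1f} h drift -> "
          f"{res.summary['percent_of_baseline']:.1f}%")

print("\nWith protein, depressed and potentiated weights stabilize in")
print("separate basins of attraction; without it both drift back toward")
print("the single baseline fixed point.")
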