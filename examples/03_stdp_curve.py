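"""The classic spike-timing-dependent plasticity curve.

A single presynaptic spike (calcium jump 0.9, below both thresholds) is
paired with a postsynaptic spike (jump 1.55) at varying intervals.
Pre-before-post rides the residual presynaptic calcium past the
potentiation threshold for longer; post-before-pre adds calcium on the
way down, extending the depressive dwell.  A lone postsynaptic spike is
nearly plasticity-neutral: its potentiation on the way up is balanced by
depression on the way down.
"""

from fplr import run_stdp_pair, stdp_sweep

lone = run_stdp_pair(-300.0, w0=1.0)
print(f"lone post spike: dw = {lone.summary['delta_w']:+.2e}  "
      f"(dwell: {lone.summary['dwell_potentiative']:.2f} ms potentiative, "
      f"{lone.summary['dwell_depressive']:.2f} ms depressive)")

table = stdp_sweep([-40, -20, -10, -5, 5, 10, 20, 40], [1.0], "stdp",
                   n_pairings=60)
print("\n60 pairings, w0 = 1:")
for _, row in table.iterrows():
    print(f"  dt = {row.delta_t:+5.0f} ms   dw = {row.delta_w:+.4f}")
print("\nPositive intervals (pre-before-post) potentiate, negative ones")
print("depress, and the effect vanishes once the calcium transients no")
print("longer overlap (|dt| >> tau_Ca = 7 ms).")
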