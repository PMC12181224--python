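"""Frequency-dependent plasticity: depression at low rates, potentiation
at high rates, and its dependence on the initial weight.

Five presynaptic spikes are delivered at each frequency.  At low
frequency each calcium transient decays independently and only grazes the
depressive region; at high frequency the transients summate past the
potentiation threshold.  Because updates are asymptotic, a synapse that
starts near the potentiative fixed point can only lose weight ("what goes
up must come down").
"""

from fplr import frequency_sweep

table = frequency_sweep(freqs=[1, 5, 10, 20, 50, 100],
                        w0s=[0.5, 1.0, 2.25], preset="frequency")

print(table.pivot(index="w0", columns="freq", values="delta_w")
      .round(3).to_string())
print("\nRows: initial weight; columns: input frequency (Hz); entries: net")
print("weight change. Note the sign flip along the frequency axis for")
print("w0 = 1 and the uniformly negative top row for w0 = 2.25 (a synapse")
print("at the potentiative fixed point can only be depressed).")
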