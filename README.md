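# fplr — fixed point–learning rate calcium plasticity

`fplr` is a Python library and simulator for calcium-controlled synaptic
plasticity under the **fixed point–learning rate (FPLR)** framework.  It
is aimed at computational neuroscientists and experimentalists who want
an interpretable, few-parameter model of long-term potentiation and
depression: instead of coupling rate and asymptote through decay terms,
you specify directly, for each region of the synaptic calcium
concentration, *where* the weight is going and *how fast*.

With depression and potentiation thresholds θ_D < θ_P partitioning the
calcium axis, the one-dimensional rule is

    Δw = η(Ca) · (F(Ca) − w)

where F(Ca) and η(Ca) are step functions giving the fixed point and
learning rate of the active region; the two-dimensional rule
η(Ca, w) · (F(Ca, w) − w) adds weight-dependent fixed points with basins
of attraction (multi-stable drift), and a protein-gated rule switches
between the two to capture protein-synthesis-dependent late-phase
stabilization.  The classical Shouval–Bear–Cooper and Graupner–Brunel
rules are included for comparison, along with spike-driven calcium
generation, dwell-time "bar codes", the canonical frequency-dependent
and spike-timing-dependent (STDP) protocols, and a
behavioral-timescale-plasticity (BTSP) place-field simulation on a
circular track.  See `docs/methods.md` for the model details and
parameter tables.

## A worked example

Probe the early-phase fixed points by holding calcium inside each region
(`examples/01_step_fixed_points.py`):

```python
from fplr import load_preset, run_step_protocol

preset = load_preset("frequency")
res = run_step_protocol(level=1.15, duration_on=500.0, duration_off=1.0,
                        w0=1.0, preset=preset)
print(res.weights.final)
```

Running the example prints:

```
   depressive hold at Ca=1.15: w 1.00 -> 0.4200 (42.0% of baseline)
 potentiative hold at Ca=1.60: w 1.00 -> 2.2500 (225.0% of baseline)
```

A synapse held at a depressive calcium level relaxes to the depressive
fixed point — 42% of its baseline strength, the level reached by
low-frequency-stimulation LTD — while a potentiative hold relaxes to
225%, the high-frequency-stimulation LTP level.  The held level only
sets the speed of approach; the asymptote is the region's fixed point.

The protein-gated late phase (`examples/04_late_phase_protein.py`)
continues from these endpoints through hours of drift:

```
LTD (protein ): early -> 42% of baseline, after 4.5 h drift -> 61.0%
LTD (no protein): early -> 42% of baseline, after 4.5 h drift -> 100.0%
LTP (protein ): early -> 225% of baseline, after 10.0 h drift -> 142.0%
LTP (no protein): early -> 225% of baseline, after 10.0 h drift -> 100.0%
```

With protein synthesis, depressed and potentiated weights stabilize in
separate basins (61% / 142% of baseline); without it, both drift back to
baseline.

The other examples cover the frequency sweep (depression at low input
rates, potentiation at high rates, sign reversal with initial weight),
the classic STDP curve, the SBC/GB/FPLR rule gallery, and the BTSP
session in which a plateau induction creates a place field, a nearby
second induction overwrites it, and a distant third one coexists.

## Command line

A thin CLI wraps the same protocols:

```bash
fplr step --level 1.15 --out out/step
fplr freq --freq-grid 1,10,100 --w0-grid 0.5,1,2.25 --out out/freq
fplr stdp --dt-grid=-20,-10,10,20 --out out/stdp
fplr late-phase --direction ltd --protein --out out/lp
fplr btsp --laps 7 --inductions 2:3500,4:2000,6:7500 --seed 1 --out out/btsp
fplr phase-plane --preset frequency --out out/pp
```

Each run writes CSV traces, a JSON summary and a manifest sufficient to
reproduce it.

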