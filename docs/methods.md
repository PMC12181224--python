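# Methods

## The model

Calcium-based plasticity is modeled phenomenologically: the synaptic
calcium concentration tells the weight *where it is going* and *how fast
it goes there*.  The calcium axis is partitioned by a depression
threshold θ_D and a potentiation threshold θ_P (plus optional extra
thresholds for neutral zones) using half-open regions [θ_i, θ_{i+1}).
Within each region the weight relaxes toward a fixed point F at a
learning rate η:

    Δw = η(Ca) · (F(Ca) − w)                 (1D rule)
    Δw = η(Ca, w) · (F(Ca, w) − w)           (2D rule)

The 1D rule generalizes the Shouval–Bear–Cooper (SBC) family (linear
two-threshold rule, rule with weight decay, rule with calcium-dependent
learning rate), which the package also implements for comparison; the 2D
rule generalizes the Graupner–Brunel (GB) bistable-efficacy rule (also
implemented, in its original cumulative-terms form and a simplified
one-process-at-a-time variant, both without the stochastic noise term).
In the 2D rule the pre-depressive region carries N weight fixed points
inside N + 1 strictly increasing basin boundaries; a weight exactly on an
interior boundary (within 10⁻¹²) is an unstable fixed point, with
half-stable variants selectable per boundary.  A protein-gated rule
dispatches between a 1D rule (no stabilizing protein: all weights drift
to one baseline) and a 2D rule (protein present: depressed and
potentiated weights stabilize in separate basins).

Both F and η are hard step functions by default; a sum-of-sigmoids soft
version with per-threshold steepness b_i is available and converges to
the hard step as b_i → ∞.  When a soft step is wanted without a stated
steepness, b = 80 per concentration unit is visually sharp at the
calcium scales used here.

## Units and integration

Learning rates are **rates per time unit** — per millisecond for the
frequency/STDP/BTSP presets, per second for the late-phase preset.  The
discrete update applies the per-step fraction η·dt, which must lie in
[0, 1] (validated at construction; η·dt = 1 jumps straight to the fixed
point, useful for discrete-state synapses).  With dt = 1 the rate and
the per-step fraction coincide, which is how the BTSP (dt = 1 ms) and
late-phase (dt = 1 s) parameter sets are written.  This convention keeps
the frequency/STDP dynamics meaningful at dt = 0.01 ms: per-pairing STDP
changes stay small (hundreds of pairings are needed for a visible
effect) and high-frequency trains potentiate rather than being erased by
the closing depression.

Under constant calcium the discrete update is an exact geometric
relaxation, w_n − F = (1 − η·dt)ⁿ (w_0 − F).  The integrator exploits
this: a hard-threshold 1D rule is integrated segment-by-segment in
closed form at machine precision (one segment per threshold crossing of
the calcium trace), which is also what makes the protocol sweeps cheap.
The continuous-time closed form w(t_E) = F + (w(t_S) − F) e^{−η_c (t_E −
t_S)} uses η_c = −ln(1 − η·dt)/dt so that it agrees exactly with the
discrete recursion at step multiples.  Soft-threshold, 2D,
protein-gated, SBC and GB rules use a per-step loop.

Calcium decays by the exact factor e^{−dt/τ_Ca} per step (not the Euler
factor 1 − dt/τ_Ca), so dwell-time arithmetic is free of integration
error; a spike's jump is added after that step's decay, so the trace
equals the full jump height at the spike sample.  Pre- and postsynaptic
spikes in the same sample sum.  Bar codes classify every sample into the
depressive [θ_D, θ_P) or potentiative [θ_P, ∞) region; their durations
are sample counts × dt and are accurate to one sample per crossing.

## Presets

| preset | dt | θ_D | θ_P | η_D | η_P | F_D | F_P | calcium |
|---|---|---|---|---|---|---|---|---|
| frequency | 0.01 ms | 1.0 | 1.3 | 0.04/ms | 0.055/ms | 0.42 | 2.25 | C_pre 1.05, τ 10 ms |
| stdp | 0.01 ms | 1.0 | 1.3 | 0.001/ms | 0.00075/ms | 0.42 | 2.25 | C_pre 0.9, C_post 1.55, τ 7 ms |
| btsp | 1 ms | 1.5 | 2.15 | 0.0017/ms | 0.15/ms | 0.2 | 2.5 | jump 0.1, plateau 1.33 × 300 ms, τ 2 s |
| late_phase_fig5 | 1 s | 1.0 | 1.3 | 1/s | 1/s | 0.42 | 2.25 | held levels, no spikes |

Pre-depressive drift is off (η = 0) in the three fast presets: the drift
timescale is orders of magnitude slower than early-phase plasticity.
The early-phase fixed points are calibrated to classic induction
experiments: low-frequency stimulation (900 pulses at 1 Hz; each pulse
gating ≈10 ms of calcium, hence a 9-s depressive signal) depresses to
42% of baseline, and high-frequency stimulation (3 × 100 pulses at
100 Hz, a 3-s potentiative signal) potentiates to 225%.

The late-phase preset drives the early phase at η = 1 per second (an
effectively instantaneous jump to the early fixed point relative to the
hours-long late phase) and then drifts at 0.0046 s⁻¹ with calcium at
zero.  Without protein the 1D drift target is baseline (1.0).  With
protein the pre-depressive basins are [0.61, 1.0, 1.42] with boundaries
[0, 0.8, 1.2, 2.5]: the outer fixed points are the experimentally
observed stabilization levels of depressed (61%) and potentiated (142%)
synapses; the middle basin holds unperturbed weights at baseline.  The
basin *boundaries* are free choices — any boundaries that separate 0.42
/ 1.0 / 2.25 into different basins give the same asymptotes.  The held
calcium levels of the early phase (1.15 and 1.6) are likewise free
within their regions, since the early phase terminates at a fixed point.
A limitation inherited from the 1D no-protein rule: LTD without protein
ends at 100% of baseline here; producing a distinct LTD-specific
endpoint (e.g. ≈92%) would require a weight-dependent (2D) no-protein
drift, which the shipped preset deliberately omits.

## Stimulation protocols

Frequency protocol: n (default 5) presynaptic spikes at 1000/f ms
intervals, first spike at 5 ms.  STDP: the earlier spike of the pair at
50 ms; the window adapts to the interval.  Both extend the simulation
past the last spike until the calcium has decayed below θ_D·(1 − 10⁻⁶),
so the depression incurred while a potentiative transient decays back
through the depressive region ("what goes up must come down") is always
part of the result.  Repeated STDP pairings tile the single-pairing
calcium trace, i.e. the calcium decays fully between pairings while the
weight carries over.

## The BTSP simulation and its synthetic inputs

A leaky-integrator neuron (C_m = 1 nF, τ_V = 15 ms, V_rest = −75 mV)
receives N = 1000 presynaptic inputs whose Gaussian receptive fields
(width r = 400 ms of track, peak Bernoulli rate P_max = 0.02 per 1-ms
step ⇒ 20 Hz at field center, matching hippocampal place-cell rates)
tile a 10-s circular track; field distance is circular, so fields near
the lap seam behave like all others.  dt = 1 ms: all time constants in
the model are ≥ 15 ms, and P_max is naturally a per-millisecond rate.
Each spike depolarizes the neuron by 0.4 mV per unit weight — the
weight-to-charge scale is a free constant chosen so a maximally
potentiated synapse (w = 2.5) produces a 1-mV single-spike EPSP.  A
plateau induction clamps the voltage to −30 mV exactly for 300 ms and
broadcasts a rectangular calcium step of height 1.33 to every synapse;
afterwards it decays with the shared τ_Ca = 2 s, a deliberate
single-time-constant stand-in for the combined cytosolic and
ER-released calcium.  Per-synapse spike calcium adds 0.1 per own spike
with the same decay.  Weights follow the 1D FPLR rule with drift off,
all synapses initialized at the depressive fixed point (0.2).

What the generator emulates: spatially tuned, stochastic, tiled inputs
at realistic rates and a supervisor-driven plateau.  What it does not:
postsynaptic spiking, separate cytosolic/ER calcium pools, conductance-
based synapses, running-speed variability, or any lock-in of
potentiation.  Consequently the simulation speaks to the *weight
dependence* of behavioral-timescale plasticity (who potentiates, who is
overwritten, who is untouched) rather than to quantitative EPSP ramps.

One consequence of honest Poisson inputs: a synapse's own calcium has
expected peak ≈1.1 (safely below θ_D = 1.5) but fluctuates, so on rare
laps a lucky spike run crosses θ_D or even θ_P without any induction.
Depressive crossings are inert (weights sit at the floor F_D, and the
rule's weight dependence means a floor synapse cannot be depressed);
rare spontaneous potentiations affect ≲2% of synapses per lap pair.
Under the default 7-lap schedule the calcium of the synapse whose field
center coincides with the lap-2 induction exceeds θ_P for ≈0.5–0.6 s on
average across seeds — the window that drives its potentiation.  The
distribution is bimodal: typical realizations give 0.6–1 s, but in
roughly a quarter of runs the spike calcium falls short and the total
never crosses θ_P.  The acceptance script recomputes this mean over 20
sessions.

Voltage ramps (place fields) are detected on a lap by boxcar-smoothing
the voltage over 200 ms and thresholding 0.5 mV above the lap's *median*
smoothed voltage — the tiled background inputs hold the membrane ≈1.7 mV
above rest everywhere, so rest is not a usable baseline; gaps and
fragments shorter than 300 ms are bridged/dropped.

Problem sizes: protocols run 10⁴–10⁶ 0.01-ms steps; the late phase runs
16 200–36 000 1-s steps; a 7-lap BTSP session is 70 000 1-ms steps over
1000 synapses, and the stochastic acceptance quantity averages 20
sessions.  All randomness flows from one `numpy` `SeedSequence` per
session; identical (configuration, seed) pairs are bit-reproducible.

## Numerical choices and degenerate inputs

* Region membership is half-open everywhere (ties at a threshold go to
  the upper region), applied uniformly across rules.
* η·dt > 1 is rejected at construction, not clamped.
* Negative calcium raises an error; λ = 0 silently reduces the SBC decay
  rule to the linear rule; an empty spike train yields a zero trace.
* Basin specifications are validated for monotone boundaries, fixed
  points strictly inside their basins, and rates in [0, 1];
  `validate_basins` returns violations rather than raising, and the
  constructors raise on any violation.
* The plasticity delay D between calcium and weight update is fixed at
  zero.
* The GB noise term is omitted; the drift cubic keeps its exact roots
  {0, w*, 1}.

## Known limitations

* The framework is first-order and deterministic: no stochastic state
  switching, no kinase/phosphatase mechanisms, no parameter fitting.
* Calcium is phenomenological (jump + exponential decay); there is no
  channel-level influx, saturation or buffering.
* The BTSP suprathreshold window sits close to θ_P, so its duration has
  a large seed-to-seed spread; treat per-seed values as realizations,
  not estimates.
* The late-phase transient *shapes* depend on the free held-calcium
  levels; only the asymptotes are calibrated.
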