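"""Canonical plasticity stimulation protocols.

Frequency-dependent plasticity, spike-timing-dependent plasticity (STDP)
and the protein-gated late-phase experiment, plus the parameter sweeps
used to map the outcome as a function of stimulation and initial weight.

All early-phase protocols integrate the 1D FPLR rule with pre-depressive
drift turned off (``eta(Ca < theta_D) = 0`` in the shipped presets) against
spike-driven calcium, and extend the simulation past the last spike until
the calcium has decayed below the depression threshold, so that the
"what goes up must come down" depression incurred while a potentiative
transient decays back through the depressive region is always included.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calcium import (
    Barcode,
    CalciumTrace,
    SpikeTrain,
    compute_barcode,
    spike_calcium,
    step_stimulus,
)
from .presets import Preset, load_preset
from .rules import (
    FPLRRule1D,
    ProteinGatedRule,
    WeightTrajectory,
    integrate_rule,
)

__all__ = [
    "ProtocolResult",
    "run_step_protocol",
    "run_frequency_protocol",
    "frequency_sweep",
    "run_stdp_pair",
    "stdp_sweep",
    "run_late_phase_experiment",
    "stimulus_calcium_duration",
    "LFS_PULSES",
    "HFS_PULSES",
]

logger = logging.getLogger(__name__)

#: Pulse counts of the canonical early-phase protocols: low-frequency
#: stimulation (900 pulses at 1 Hz, LTD) and high-frequency stimulation
#: (3 trains of 100 pulses at 100 Hz, LTP).
LFS_PULSES = 900
HFS_PULSES = 300

#: Assumed duration of the calcium transient of a single stimulation pulse.
PULSE_CALCIUM_MS = 10.0

# relative margin below theta_D at which a decaying trace counts as "down"
_TAIL_MARGIN = 1e-6


@dataclass
class ProtocolResult:
    """Outcome of one protocol run: traces, bar code, and summary."""

    calcium: CalciumTrace
    weights: WeightTrajectory
    barcode: Barcode
    summary: dict

    def __post_init__(self):
        # keep the summary's delta_w consistent with the trajectory
        self.summary.setdefault("w0", self.weights.initial)
        self.summary["w_final"] = self.weights.final
        self.summary["delta_w"] = self.summary["w_final"] - self.summary.get(
            "w_start", self.summary["w0"]
        )


def stimulus_calcium_duration(n_pulses: int,
                              pulse_ms: float = PULSE_CALCIUM_MS) -> float:
    """Total early-phase calcium duration of a pulse train, in seconds.

    Each stimulation pulse is assumed to gate a ~10 ms calcium transient,
    so e.g. 900 LFS pulses keep calcium elevated for 9 s in total and 300
    HFS pulses for 3 s; these durations set the early-phase hold times of
    the late-phase experiment.
    """
    if n_pulses < 0:
        raise ValueError("pulse count must be non-negative")
    return n_pulses * pulse_ms / 1000.0


def _resolve_preset(preset, default_name: str) -> Preset:
    if preset is None:
        return load_preset(default_name)
    if isinstance(preset, Preset):
        return preset
    return load_preset(preset)


def _tail_after_last_spike(peak: float, theta_D: float, tau: float) -> float:
    """Decay time from the post-spike peak down past theta_D (with margin)."""
    target = theta_D * (1.0 - _TAIL_MARGIN)
    if peak <= target:
        return 0.0
    return tau * math.log(peak / target)


def _run_spike_protocol(pre: SpikeTrain, post: Optional[SpikeTrain],
                        preset: Preset, w0: float) -> ProtocolResult:
    """Shared machinery: spikes -> calcium -> weight trajectory -> barcode."""
    params = preset.calcium
    rule: FPLRRule1D = preset.rule
    all_times = np.sort(np.concatenate(
        [pre.times] + ([post.times] if post is not None else [])))
    # worst-case calcium right after the last spike, by superposition
    last = all_times[-1]
    peak = 0.0
    for train, height in ((pre, params.C_pre), (post, params.C_post)):
        if train is None:
            continue
        peak += height * float(np.sum(np.exp(-(last - train.times) / params.tau_Ca)))
    tail = _tail_after_last_spike(peak, rule.thresholds.theta_D, params.tau_Ca)
    T = last + tail + 2 * rule.dt
    logger.debug("spike protocol: %d spikes, last at %.2f, decay tail %.2f",
                 all_times.size, last, tail)
    trace = spike_calcium(pre, post, params, T, rule.dt)
    weights = integrate_rule(trace, w0, rule)
    barcode = compute_barcode(trace, rule.thresholds)
    logger.debug("dwell: depressive %.3f, potentiative %.3f; w %.4f -> %.4f",
                 barcode.depressive_duration, barcode.potentiative_duration,
                 w0, weights.final)
    summary = {
        "w0": w0,
        "dwell_depressive": barcode.depressive_duration,
        "dwell_potentiative": barcode.potentiative_duration,
    }
    return ProtocolResult(trace, weights, barcode, summary)


def run_step_protocol(level: float, duration_on: float, duration_off: float,
                      w0: float, preset) -> ProtocolResult:
    """Hold calcium at ``level`` and then at zero; the fixed-point probe.

    The asymptote during the hold reveals the fixed point of the region
    containing ``level``; the post-hold segment exposes any drift.
    """
    preset = _resolve_preset(preset, "frequency")
    rule = preset.rule
    trace = step_stimulus(level, 0.0, duration_on,
                          duration_on + duration_off, rule.dt)
    weights = integrate_rule(trace, w0, rule)
    barcode = compute_barcode(trace, rule.thresholds)
    return ProtocolResult(trace, weights, barcode, {"w0": w0, "level": level})


def run_frequency_protocol(freq: float, n_spikes: int = 5,
                           w0: Optional[float] = None,
                           preset=None,
                           start: float = 5.0) -> ProtocolResult:
    """Train of presynaptic spikes at a fixed frequency.

    ``n_spikes`` presynaptic inputs are delivered every ``1000 / freq`` ms.
    At low frequency each calcium transient decays almost fully between
    spikes and only grazes the depressive region; at high frequency the
    transients summate above the potentiation threshold.  The simulation
    runs until the calcium has decayed below ``theta_D`` after the last
    spike, so the closing depressive dwell is part of the result.
    """
    if freq <= 0:
        raise ValueError("stimulation frequency must be positive")
    if n_spikes < 1:
        raise ValueError("need at least one spike")
    preset = _resolve_preset(preset, "frequency")
    if w0 is None:
        w0 = preset.w0
    interval = 1000.0 / freq
    pre = SpikeTrain(start + interval * np.arange(n_spikes))
    result = _run_spike_protocol(pre, None, preset, w0)
    result.summary["freq"] = freq
    result.summary["n_spikes"] = n_spikes
    return result


def frequency_sweep(freqs: Sequence[float], w0s: Sequence[float],
                    preset=None, n_spikes: int = 5) -> pd.DataFrame:
    """Net weight change and dwell times over a (frequency x w0) grid.

    Returns one row per grid cell with columns ``freq``, ``w0``,
    ``delta_w``, ``w_final``, ``dwell_depressive``, ``dwell_potentiative``.
    The calcium trace is computed once per frequency and shared across
    initial weights.
    """
    preset = _resolve_preset(preset, "frequency")
    rows = []
    for freq in freqs:
        base = run_frequency_protocol(freq, n_spikes=n_spikes,
                                      w0=float(w0s[0]), preset=preset)
        for w0 in w0s:
            if w0 == w0s[0]:
                res_weights = base.weights
            else:
                res_weights = integrate_rule(base.calcium, float(w0), preset.rule)
            rows.append({
                "freq": freq,
                "w0": float(w0),
                "delta_w": res_weights.final - float(w0),
                "w_final": res_weights.final,
                "dwell_depressive": base.barcode.depressive_duration,
                "dwell_potentiative": base.barcode.potentiative_duration,
            })
    return pd.DataFrame(rows)


def run_stdp_pair(delta_t: float, w0: Optional[float] = None,
                  preset=None, n_pairings: int = 1) -> ProtocolResult:
    """One (or more) pre/post spike pairings at interval ``delta_t``.

    Positive ``delta_t``: the presynaptic spike leads the postsynaptic one
    (pre-before-post); negative: post-before-pre.  The earlier spike is
    placed at 50 ms and the simulation extends until the calcium has
    decayed below ``theta_D``.  With ``n_pairings > 1`` the pairing is
    repeated after full calcium decay, the weight carrying over.
    """
    preset = _resolve_preset(preset, "stdp")
    if w0 is None:
        w0 = preset.w0
    if n_pairings < 1:
        raise ValueError("n_pairings must be >= 1")
    t_first = 50.0
    if delta_t >= 0:
        t_pre, t_post = t_first, t_first + delta_t
    else:
        t_post, t_pre = t_first, t_first - delta_t
    pre = SpikeTrain([t_pre])
    post = SpikeTrain([t_post])
    single = _run_spike_protocol(pre, post, preset, float(w0))
    if n_pairings == 1:
        result = single
    else:
        ca = CalciumTrace(np.tile(single.calcium.values, n_pairings),
                          single.calcium.dt)
        weights = integrate_rule(ca, float(w0), preset.rule)
        barcode = compute_barcode(ca, preset.rule.thresholds)
        result = ProtocolResult(ca, weights, barcode, {
            "w0": float(w0),
            "dwell_depressive": barcode.depressive_duration,
            "dwell_potentiative": barcode.potentiative_duration,
        })
    result.summary["delta_t"] = delta_t
    result.summary["n_pairings"] = n_pairings
    return result


def stdp_sweep(delta_ts: Sequence[float], w0s: Sequence[float],
               preset=None, n_pairings: int = 1) -> pd.DataFrame:
    """STDP curve/heatmap: weight change per (pairing interval x w0)."""
    preset = _resolve_preset(preset, "stdp")
    rows = []
    for dt_pair in delta_ts:
        base = run_stdp_pair(dt_pair, w0=float(w0s[0]), preset=preset,
                             n_pairings=n_pairings)
        for w0 in w0s:
            if w0 == w0s[0]:
                weights = base.weights
            else:
                weights = integrate_rule(base.calcium, float(w0), preset.rule)
            rows.append({
                "delta_t": dt_pair,
                "w0": float(w0),
                "delta_w": weights.final - float(w0),
                "w_final": weights.final,
                "dwell_depressive": base.barcode.depressive_duration,
                "dwell_potentiative": base.barcode.potentiative_duration,
            })
    return pd.DataFrame(rows)


def run_late_phase_experiment(direction: str, protein: bool,
                              rule: Optional[ProteinGatedRule] = None,
                              durations: Optional[dict] = None,
                              preset=None) -> ProtocolResult:
    """Early-phase induction followed by hours of protein-gated drift.

    Phase 1 holds calcium inside the depressive (``direction="ltd"``, 9 s)
    or potentiative (``direction="ltp"``, 3 s) region with a one-second
    learning rate of 1, driving the weight to the early fixed point (42% or
    225% of baseline).  Phase 2 sets calcium to zero for hours (LTD: 4.5 h,
    LTP: 10 h) while the weight drifts at 0.0046 per second -- back to
    baseline without protein, or into the stabilized basin (61% / 142% of
    baseline) with protein present.

    Because the early phase ends exactly at a region fixed point, the
    asymptotes are insensitive to the exact held calcium levels.
    """
    direction = direction.lower()
    if direction not in ("ltp", "ltd"):
        raise ValueError(f"unknown direction {direction!r}; use 'ltp' or 'ltd'")
    preset = _resolve_preset(preset, "late_phase_fig5")
    if rule is None:
        rule = preset.rule
    proto = dict(preset.raw.get("protocol", {}))
    if durations:
        proto.update(durations)
    level = proto[f"{direction}_hold_level"]
    early_s = float(proto[f"{direction}_early_duration_s"])
    late_s = float(proto[f"{direction}_late_duration_s"])
    dt = rule.dt
    n_early = int(round(early_s / dt))
    n_late = int(round(late_s / dt))
    ca = CalciumTrace(
        np.concatenate([np.full(n_early, float(level)), np.zeros(n_late)]), dt
    )
    logger.debug("late phase %s: hold Ca=%.3f for %g s, then 0 for %g s "
                 "(protein=%s)", direction, level, early_s, late_s, protein)
    protein_trace = np.full(ca.values.size, 1 if protein else 0, dtype=int)
    w0 = preset.w0
    weights = integrate_rule(ca, w0, rule, protein_trace=protein_trace)
    barcode = compute_barcode(ca, rule.thresholds)
    summary = {
        "w0": w0,
        "direction": direction,
        "protein": bool(protein),
        "early_duration_s": early_s,
        "late_duration_s": late_s,
        "w_after_early": float(weights.values[n_early - 1]),
        "percent_of_baseline": 100.0 * weights.final / w0,
    }
    return ProtocolResult(ca, weights, barcode, summary)
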