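"""Behavioral-timescale plasticity (BTSP) on a circular track.

A leaky-integrator neuron receives Bernoulli spikes from ``N`` spatially
tuned presynaptic inputs whose Gaussian receptive fields tile a circular
track; a supervising signal can clamp the voltage to a plateau and
broadcast a rectangular calcium step to every synapse.  Each synapse sees
the sum of its own spike-driven calcium and the global plateau calcium,
both decaying with a single long time constant (~2 s) that stands in for
the combined cytosolic and endoplasmic-reticulum calcium.  Synaptic
weights follow the 1D FPLR rule with pre-depressive drift off, so a
plateau induction potentiates synapses whose fields coincide with it and
can only depress synapses that were previously potentiated above the
depressive fixed point -- the mechanism behind place-field formation and
overwriting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .presets import load_preset
from .rules import FPLRRule1D

__all__ = [
    "NeuronParams",
    "TrackConfig",
    "BTSPCalciumParams",
    "BTSPSession",
    "receptive_field_rate",
    "sample_spikes",
    "neuron_step",
    "synapse_calcium_step",
    "run_btsp_session",
    "detect_ramps",
    "weight_change_map",
]

logger = logging.getLogger(__name__)

DEFAULT_INDUCTIONS = {2: 3500.0, 4: 2000.0, 6: 7500.0}
MIRROR_INDUCTIONS = {2: 6500.0, 4: 8000.0, 6: 2500.0}


@dataclass(frozen=True)
class NeuronParams:
    """Leaky-integrator neuron.

    ``C_m`` membrane capacitance (nF), ``tau_V`` leak time constant (ms),
    ``V_rest``/``V_plateau`` in mV.  ``epsp_per_unit_weight`` converts a
    unit-weight presynaptic spike into an instantaneous depolarization
    (mV); at 0.4 mV a maximally potentiated synapse (w = 2.5) produces a
    single-spike EPSP of 1 mV.
    """

    C_m: float = 1.0
    tau_V: float = 15.0
    V_rest: float = -75.0
    V_plateau: float = -30.0
    epsp_per_unit_weight: float = 0.4

    def __post_init__(self):
        if self.tau_V <= 0:
            raise ValueError("tau_V must be positive")
        if self.V_plateau <= self.V_rest:
            raise ValueError("V_plateau must exceed V_rest")


@dataclass(frozen=True)
class TrackConfig:
    """Circular track and spatially tuned inputs.

    ``T`` lap duration in ms (locations are expressed as milliseconds of
    constant-velocity running), ``N`` synapses with Gaussian receptive
    fields of width ``r`` (ms of track) whose centers tile the track every
    ``T / N`` ms, and peak per-step spike probability ``P_max``.
    """

    T: float = 10_000.0
    N: int = 1000
    r: float = 400.0
    P_max: float = 0.02

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("need at least one synapse")
        if not (0.0 <= self.P_max <= 1.0):
            raise ValueError("P_max must lie in [0, 1]")
        if self.r <= 0 or self.T <= 0:
            raise ValueError("r and T must be positive")

    @property
    def field_centers(self) -> np.ndarray:
        return np.arange(self.N) * self.T / self.N


@dataclass(frozen=True)
class BTSPCalciumParams:
    """Dual-source synaptic calcium for BTSP.

    A presynaptic spike adds ``pre_height`` to its own synapse; a plateau
    induction holds ``plateau_height`` at every synapse for
    ``plateau_duration`` ms.  Both components decay with the shared slow
    ``tau_Ca`` (ms) once their drive ends.
    """

    pre_height: float = 0.1
    plateau_height: float = 1.33
    plateau_duration: float = 300.0
    tau_Ca: float = 2000.0

    def __post_init__(self):
        for name in ("pre_height", "plateau_height", "plateau_duration", "tau_Ca"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def receptive_field_rate(l_i, l, cfg: TrackConfig):
    """Per-step spike probability of a field centered at ``l_i``.

    Gaussian in the *circular* track distance, so a field near the lap
    seam responds on both sides of it: distance is
    ``min(|l_i - l|, T - |l_i - l|)``.
    """
    diff = np.abs(np.asarray(l_i, dtype=float) - np.asarray(l, dtype=float))
    dist = np.minimum(diff, cfg.T - diff)
    return cfg.P_max * np.exp(-((dist / cfg.r) ** 2))


def rate_matrix(cfg: TrackConfig, dt: float) -> np.ndarray:
    """(steps-per-lap, N) matrix of spike probabilities over one lap."""
    steps = int(round(cfg.T / dt))
    locations = (np.arange(steps) * dt) % cfg.T
    return receptive_field_rate(cfg.field_centers[None, :],
                                locations[:, None], cfg)


def sample_spikes(rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli spikes per step and synapse (reproducible)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates > 1.0) or np.any(rates < 0.0):
        raise ValueError("spike probabilities must lie in [0, 1]")
    return rng.random(rates.shape) < rates


def neuron_step(V: float, syn_input: float, plateau_active: bool,
                params: NeuronParams, dt: float) -> float:
    """Advance the membrane voltage by one step.

    During a plateau induction the voltage is clamped exactly to
    ``V_plateau`` (the plateau current cancels all other currents);
    otherwise the voltage leaks toward ``V_rest`` with ``tau_V`` and each
    presynaptic spike at synapse ``i`` kicks it up by
    ``epsp_per_unit_weight * w_i`` (``syn_input`` is the spike-weighted sum
    ``sum_i w_i s_i``).
    """
    if plateau_active:
        return params.V_plateau
    return V + (dt / params.tau_V) * (params.V_rest - V) \
        + params.epsp_per_unit_weight * syn_input


def synapse_calcium_step(ca_pre: np.ndarray, spikes: np.ndarray,
                         ca_plateau: float, plateau_active: bool,
                         params: BTSPCalciumParams, dt: float):
    """Advance per-synapse calcium by one step.

    Per-synapse spike calcium decays by the exact factor
    ``exp(-dt / tau_Ca)`` and jumps by ``pre_height`` on its own spikes;
    the plateau component is held at ``plateau_height`` while the
    induction is active and decays with the same constant afterwards.  The
    plateau calcium is broadcast identically to all synapses; total
    calcium is ``ca_pre + ca_plateau``.
    """
    decay = math.exp(-dt / params.tau_Ca)
    ca_pre = ca_pre * decay + params.pre_height * np.asarray(spikes, dtype=float)
    if plateau_active:
        ca_plateau = params.plateau_height
    else:
        ca_plateau = ca_plateau * decay
    return ca_pre, ca_plateau


@dataclass
class BTSPSession:
    """Recorded state of a multi-lap place-field experiment.

    Full-resolution voltage, per-synapse weight and total-calcium matrices
    recorded every ``record_stride`` steps, exact per-lap dwell counts in
    the depressive and potentiative calcium regions for every synapse, and
    full-resolution traces for a handful of tracked synapses.
    """

    dt: float
    lap_duration: float
    laps: int
    inductions: Dict[int, float]
    seed: int
    voltage: np.ndarray                 # (laps * steps,)
    weights: np.ndarray                 # (n_records, N), every record_stride
    calcium: np.ndarray                 # (n_records, N)
    record_stride: int
    dwell_depressive: np.ndarray        # (laps, N) in time units
    dwell_potentiative: np.ndarray      # (laps, N)
    tracked: Dict[int, dict]            # synapse -> full Ca/weight arrays
    final_weights: np.ndarray           # (N,)
    config: TrackConfig
    neuron: NeuronParams
    ca_params: BTSPCalciumParams

    @property
    def steps_per_lap(self) -> int:
        return int(round(self.lap_duration / self.dt))

    def lap_voltage(self, lap: int) -> np.ndarray:
        """Voltage trace of a 1-based lap."""
        s = (lap - 1) * self.steps_per_lap
        return self.voltage[s:s + self.steps_per_lap]

    def synapse_at(self, location: float) -> int:
        """Index of the synapse whose field center is nearest ``location``."""
        spacing = self.lap_duration / self.config.N
        return int(round(location / spacing)) % self.config.N


def _plateau_trace(carry: float, steps: int, window, params: BTSPCalciumParams,
                   dt: float) -> np.ndarray:
    """Plateau calcium over one lap given the carried-in value."""
    decay = math.exp(-dt / params.tau_Ca)
    out = np.empty(steps)
    ca = carry
    if window is None:
        # pure decay: vectorized
        out[:] = carry * decay ** np.arange(1, steps + 1)
        return out
    a, b = window
    k = np.arange(steps)
    out[:a] = carry * decay ** (k[:a] + 1)
    out[a:b] = params.plateau_height
    out[b:] = params.plateau_height * decay ** (k[b:] - b + 1)
    return out


def run_btsp_session(laps: int = 7,
                     inductions: Optional[Dict[int, float]] = None,
                     cfg: Optional[TrackConfig] = None,
                     neuron: Optional[NeuronParams] = None,
                     ca_params: Optional[BTSPCalciumParams] = None,
                     preset=None,
                     seed: int = 0,
                     w0: Optional[float] = None,
                     record_stride: int = 10,
                     track_synapses: Optional[Sequence[int]] = None) -> BTSPSession:
    """Simulate a multi-lap place-field experiment.

    ``inductions`` maps 1-based lap numbers to plateau onset times within
    the lap (ms); the default schedule induces at 3.5 s (lap 2), 2 s
    (lap 4) and 7.5 s (lap 6).  All synapses start at the depressive fixed
    point unless ``w0`` is given.  One master ``seed`` drives all spike
    sampling; identical (configuration, seed) pairs reproduce the session
    bit for bit.
    """
    if preset is None or isinstance(preset, str):
        preset = load_preset(preset or "btsp")
    rule: FPLRRule1D = preset.rule
    raw = preset.raw
    cfg = cfg or TrackConfig(**raw.get("track", {}))
    neuron = neuron or NeuronParams(**raw.get("neuron", {}))
    ca_params = ca_params or BTSPCalciumParams(**raw.get("btsp_calcium", {}))
    dt = rule.dt
    inductions = DEFAULT_INDUCTIONS if inductions is None else dict(inductions)
    for lap, t_ind in inductions.items():
        if not (1 <= lap <= laps):
            raise ValueError(f"induction lap {lap} outside 1..{laps}")
        if not (0 <= t_ind < cfg.T):
            raise ValueError(f"induction time {t_ind} outside the lap [0, {cfg.T})")

    theta_D = rule.thresholds.theta_D
    theta_P = rule.thresholds.theta_P
    eta = np.asarray(rule.eta.values) * dt      # per-step fractions per region
    F = np.asarray(rule.F.values)
    if w0 is None:
        w0 = float(raw.get("w0", F[1]))

    steps = int(round(cfg.T / dt))
    rates = rate_matrix(cfg, dt)
    rng = np.random.default_rng(seed)
    spacing = cfg.T / cfg.N
    if track_synapses is None:
        track_synapses = sorted(
            {int(round(t / spacing)) % cfg.N for t in inductions.values()})

    n_plat = int(round(ca_params.plateau_duration / dt))
    decay = math.exp(-dt / ca_params.tau_Ca)

    w = np.full(cfg.N, float(w0))
    ca_pre = np.zeros(cfg.N)
    plat_carry = 0.0
    V = neuron.V_rest
    epsp = neuron.epsp_per_unit_weight

    voltage = np.empty(laps * steps)
    n_rec = (laps * steps) // record_stride
    weights_rec = np.empty((n_rec, cfg.N))
    calcium_rec = np.empty((n_rec, cfg.N))
    dwell_dep = np.zeros((laps, cfg.N))
    dwell_pot = np.zeros((laps, cfg.N))
    track_idx = np.asarray(sorted(track_synapses), dtype=int)
    tracked_ca = np.empty((laps * steps, track_idx.size))
    tracked_w = np.empty((laps * steps, track_idx.size))
    rec_i = 0

    for lap in range(1, laps + 1):
        spikes = sample_spikes(rates, rng)
        # per-synapse spike calcium: exact exponential filter over the lap
        zi = (ca_pre * decay)[None, :]
        ca_pre_lap, zf = lfilter([ca_params.pre_height], [1.0, -decay],
                                 spikes.astype(float), axis=0, zi=zi)
        ca_pre = ca_pre_lap[-1].copy()
        window = None
        if lap in inductions:
            a = int(round(inductions[lap] / dt))
            window = (a, min(a + n_plat, steps))
            logger.debug("lap %d: plateau induction at %.0f ms", lap,
                         inductions[lap])
        plat = _plateau_trace(plat_carry, steps, window, ca_params, dt)
        plat_carry = float(plat[-1])
        total = ca_pre_lap + plat[:, None]

        dep_mask = (total >= theta_D) & (total < theta_P)
        pot_mask = total >= theta_P
        dwell_dep[lap - 1] = dep_mask.sum(axis=0) * dt
        dwell_pot[lap - 1] = pot_mask.sum(axis=0) * dt
        dep_any = dep_mask.any(axis=1)
        pot_any = pot_mask.any(axis=1)

        base = (lap - 1) * steps
        if window is None and not dep_any.any() and not pot_any.any():
            # quiescent lap: weights frozen, membrane fully vectorizable
            drive = (dt / neuron.tau_V) * neuron.V_rest \
                + epsp * (spikes.astype(float) @ w)
            leak = 1.0 - dt / neuron.tau_V
            v_lap, _ = lfilter([1.0], [1.0, -leak], drive, zi=[leak * V])
            V = float(v_lap[-1])
            voltage[base:base + steps] = v_lap
            tracked_w[base:base + steps] = w[track_idx]
            rec = np.arange(steps)[(base + np.arange(steps)) % record_stride == 0]
            n_take = min(rec.size, n_rec - rec_i)
            weights_rec[rec_i:rec_i + n_take] = w
            calcium_rec[rec_i:rec_i + n_take] = total[rec[:n_take]]
            rec_i += n_take
        else:
            for k in range(steps):
                if dep_any[k]:
                    dep = dep_mask[k]
                    w[dep] += eta[1] * (F[1] - w[dep])
                if pot_any[k]:
                    pot = pot_mask[k]
                    w[pot] += eta[2] * (F[2] - w[pot])
                plateau_now = window is not None and window[0] <= k < window[1]
                sp = spikes[k]
                syn_input = float(w[sp].sum()) if sp.any() else 0.0
                V = neuron_step(V, syn_input, plateau_now, neuron, dt)
                voltage[base + k] = V
                if (base + k) % record_stride == 0 and rec_i < n_rec:
                    weights_rec[rec_i] = w
                    calcium_rec[rec_i] = total[k]
                    rec_i += 1
                tracked_w[base + k] = w[track_idx]
        tracked_ca[base:base + steps] = total[:, track_idx]

    tracked = {int(s): {"calcium": tracked_ca[:, j], "weight": tracked_w[:, j]}
               for j, s in enumerate(track_idx)}
    return BTSPSession(
        dt=dt, lap_duration=cfg.T, laps=laps, inductions=inductions,
        seed=seed, voltage=voltage, weights=weights_rec[:rec_i],
        calcium=calcium_rec[:rec_i], record_stride=record_stride,
        dwell_depressive=dwell_dep, dwell_potentiative=dwell_pot,
        tracked=tracked, final_weights=w.copy(), config=cfg, neuron=neuron,
        ca_params=ca_params,
    )


def detect_ramps(session: BTSPSession, lap: int, smooth_ms: float = 200.0,
                 threshold_mv: float = 0.5, min_duration_ms: float = 300.0) -> list:
    """Voltage-ramp (place-field) intervals of a lap, in seconds.

    The lap's voltage is boxcar-smoothed over ``smooth_ms`` (edge-padded to
    avoid boundary dips) and compared against the lap's median smoothed
    voltage plus ``threshold_mv``; contiguous supra-threshold stretches are
    returned as ``(t_start_s, t_end_s)`` intervals.  The median is used as
    baseline because the spatially tiled background inputs keep the
    voltage a little above rest everywhere.  Gaps shorter than
    ``min_duration_ms`` are bridged and fragments shorter than it dropped.
    """
    v = session.lap_voltage(lap)
    win = max(1, int(round(smooth_ms / session.dt)))
    kernel = np.ones(win) / win
    padded_v = np.pad(v, win, mode="edge")
    smooth = np.convolve(padded_v, kernel, mode="same")[win:-win]
    baseline = float(np.median(smooth))
    mask = smooth > baseline + threshold_mv
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    intervals = list(zip(edges[::2], edges[1::2]))
    min_steps = min_duration_ms / session.dt
    merged = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < min_steps:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [
        (s * session.dt / 1000.0, e * session.dt / 1000.0)
        for s, e in merged if e - s >= min_steps
    ]


def _single_lap_calcium(cfg: TrackConfig, ca_params: BTSPCalciumParams,
                        induction_time: float, dt: float, theta_D: float,
                        rng: np.random.Generator) -> np.ndarray:
    """(steps + tail, N) total calcium for one lap with one induction."""
    steps = int(round(cfg.T / dt))
    rates = rate_matrix(cfg, dt)
    spikes = sample_spikes(rates, rng).astype(float)
    decay = math.exp(-dt / ca_params.tau_Ca)
    ca_pre, zf = lfilter([ca_params.pre_height], [1.0, -decay], spikes,
                         axis=0, zi=np.zeros((1, cfg.N)))
    a = int(round(induction_time / dt))
    window = (a, min(a + int(round(ca_params.plateau_duration / dt)), steps))
    plat = _plateau_trace(0.0, steps, window, ca_params, dt)
    total = ca_pre + plat[:, None]
    # decay tail (no further spikes) until everything is below theta_D
    peak = float(total[-1].max())
    if peak > theta_D:
        n_tail = int(math.ceil(ca_params.tau_Ca / dt * math.log(peak / theta_D))) + 1
        k = np.arange(1, n_tail + 1)
        tail = total[-1][None, :] * (decay ** k)[:, None]
        total = np.vstack([total, tail])
    return total


def weight_change_map(w0_grid: Sequence[float],
                      distance_grid: Sequence[float],
                      cfg: Optional[TrackConfig] = None,
                      ca_params: Optional[BTSPCalciumParams] = None,
                      preset=None,
                      seeds: Sequence[int] = (0,),
                      induction_time: float = 5000.0):
    """Mean weight change vs initial weight and field distance to induction.

    Simulates a single lap with a plateau induced mid-lap and, for each
    (initial weight, field-center distance) cell, integrates the FPLR rule
    on the calcium of the synapse at that distance, averaging the final
    weight change over ``seeds``.  Near-field synapses potentiate from low
    initial weights but are net-depressed from high ones ("what goes up
    must come down"); far-field synapses barely change from low weights
    and depress slightly from high ones.

    Returns a pandas DataFrame with columns ``distance``, ``w0``,
    ``delta_w``.
    """
    import pandas as pd

    from .calcium import CalciumTrace
    from .rules import integrate_rule

    if preset is None or isinstance(preset, str):
        preset = load_preset(preset or "btsp")
    rule: FPLRRule1D = preset.rule
    raw = preset.raw
    cfg = cfg or TrackConfig(**raw.get("track", {}))
    ca_params = ca_params or BTSPCalciumParams(**raw.get("btsp_calcium", {}))
    dt = rule.dt
    spacing = cfg.T / cfg.N
    syn_idx = [int(round((induction_time + d) / spacing)) % cfg.N
               for d in distance_grid]

    acc = np.zeros((len(distance_grid), len(w0_grid)))
    for seed in seeds:
        rng = np.random.default_rng(seed)
        total = _single_lap_calcium(cfg, ca_params, induction_time, dt,
                                    rule.thresholds.theta_D, rng)
        for i, s in enumerate(syn_idx):
            trace = CalciumTrace(total[:, s], dt)
            for j, w0 in enumerate(w0_grid):
                traj = integrate_rule(trace, float(w0), rule)
                acc[i, j] += traj.final - float(w0)
    acc /= len(seeds)
    rows = [
        {"distance": float(d), "w0": float(w0), "delta_w": acc[i, j]}
        for i, d in enumerate(distance_grid)
        for j, w0 in enumerate(w0_grid)
    ]
    return pd.DataFrame(rows)
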