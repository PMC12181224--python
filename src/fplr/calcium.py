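"""Calcium traces: step stimuli, spike-driven transients and bar codes.

Calcium is modeled phenomenologically: it jumps by a fixed amount per
presynaptic or postsynaptic spike and decays exponentially toward zero with
time constant ``tau_Ca``.  A "bar code" summarizes a trace as the time
intervals during which calcium sits in the depressive or potentiative
region, whose total durations largely determine the net plastic effect of
a stimulation protocol.

Discrete convention: per step the trace first decays by the exact factor
``exp(-dt / tau_Ca)`` and then receives any spike jumps landing in that
sample, so the trace equals the full jump height at the spike sample
itself.  Pre- and postsynaptic spikes landing in the same sample sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .rules import Thresholds

__all__ = [
    "CalciumTrace",
    "CalciumParams",
    "SpikeTrain",
    "Barcode",
    "step_stimulus",
    "spike_calcium",
    "compute_barcode",
]


@dataclass
class CalciumTrace:
    """Uniformly sampled calcium concentration time series."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        return self.values.size * self.dt


@dataclass(frozen=True)
class CalciumParams:
    """Spike-calcium parameters: per-spike jumps and the decay constant.

    ``C_pre`` and ``C_post`` are the calcium jumps (arbitrary concentration
    units) caused by a presynaptic and a postsynaptic spike; ``tau_Ca`` is
    the exponential decay time constant in the trace's time units (ms for
    the shipped presets).
    """

    C_pre: float
    C_post: float
    tau_Ca: float

    def __post_init__(self):
        if self.tau_Ca <= 0:
            raise ValueError("tau_Ca must be positive")
        if self.C_pre < 0 or self.C_post < 0:
            raise ValueError("calcium jumps must be non-negative")


@dataclass
class SpikeTrain:
    """Strictly increasing spike times within ``[0, T]`` (same units as dt)."""

    times: np.ndarray

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and t[0] < 0:
            raise ValueError("spike times must be non-negative")
        self.times = t

    def __len__(self) -> int:
        return self.times.size

    def indices(self, dt: float) -> np.ndarray:
        """Sample index containing each spike (floor snapping)."""
        return np.floor(self.times / dt + 1e-9).astype(int)


@dataclass
class Barcode:
    """Plasticity bar code: dwell intervals per calcium region.

    ``depressive`` and ``potentiative`` are lists of half-open
    ``(t_start, t_end)`` intervals in trace time units; the total durations
    are the number of samples in each region times ``dt``.
    """

    depressive: list
    potentiative: list
    dt: float

    @property
    def depressive_duration(self) -> float:
        return float(sum(e - s for s, e in self.depressive))

    @property
    def potentiative_duration(self) -> float:
        return float(sum(e - s for s, e in self.potentiative))

    def to_dict(self) -> dict:
        return {
            "depressive_intervals": [list(iv) for iv in self.depressive],
            "potentiative_intervals": [list(iv) for iv in self.potentiative],
            "depressive_duration": self.depressive_duration,
            "potentiative_duration": self.potentiative_duration,
            "dt": self.dt,
        }


def step_stimulus(level: float, t_start: float, t_end: float,
                  T_total: float, dt: float) -> CalciumTrace:
    """Rectangular calcium step: ``level`` on ``[t_start, t_end)``, else 0.

    The canonical fixed-point-probing experiment holds calcium at a chosen
    level for minutes, then drops it to zero to expose drift dynamics.
    """
    if not (0 <= t_start < t_end <= T_total):
        raise ValueError("require 0 <= t_start < t_end <= T_total")
    n = int(round(T_total / dt))
    t = np.arange(n) * dt
    values = np.where((t >= t_start) & (t < t_end), float(level), 0.0)
    return CalciumTrace(values, dt)


def spike_calcium(pre: Optional[SpikeTrain], post: Optional[SpikeTrain],
                  params: CalciumParams, T: float, dt: float) -> CalciumTrace:
    """Calcium trace driven by pre- and postsynaptic spike trains.

    Each presynaptic spike adds ``C_pre`` and each postsynaptic spike adds
    ``C_post`` at the sample containing it; between spikes the trace decays
    exponentially with ``tau_Ca``.  The trace is linear in the spike
    trains: the trace of merged trains equals the sum of the separate
    traces.
    """
    n = int(round(T / dt))
    jumps = np.zeros(n)
    for train, height in ((pre, params.C_pre), (post, params.C_post)):
        if train is None or len(train) == 0:
            continue
        idx = train.indices(dt)
        if np.any(idx >= n):
            raise ValueError("spike beyond the simulated duration")
        np.add.at(jumps, idx, height)
    decay = np.exp(-dt / params.tau_Ca)
    values = lfilter([1.0], [1.0, -decay], jumps)
    return CalciumTrace(values, dt)


def _intervals_from_mask(mask: np.ndarray, dt: float) -> list:
    """Half-open time intervals covering the True runs of a boolean mask."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [
        (float(s * dt), float(e * dt))
        for s, e in zip(edges[::2], edges[1::2])
    ]


def compute_barcode(trace: CalciumTrace, thresholds: Thresholds) -> Barcode:
    """Bar code of a trace: when calcium sits in each plasticity region.

    Every sample is assigned to exactly one region by the half-open
    convention ``[theta_D, theta_P)`` / ``[theta_P, inf)``; durations equal
    sample counts times ``dt`` and are therefore accurate to one sample per
    threshold crossing.
    """
    ca = trace.values
    if np.any(ca < 0):
        raise ValueError("calcium concentration cannot be negative")
    dep = (ca >= thresholds.theta_D) & (ca < thresholds.theta_P)
    pot = ca >= thresholds.theta_P
    return Barcode(
        depressive=_intervals_from_mask(dep, trace.dt),
        potentiative=_intervals_from_mask(pot, trace.dt),
        dt=trace.dt,
    )
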