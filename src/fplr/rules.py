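"""Calcium-based plasticity rules.

This module defines the plasticity rules of the fixed point-learning rate
(FPLR) framework together with the two classical rule families it
generalizes:

* the Shouval-Bear-Cooper (SBC) family -- linear two-threshold rule, rule
  with weight decay, and rule with a calcium-dependent learning rate;
* the Graupner-Brunel (GB) bistable-efficacy rule and its simplified,
  one-process-at-a-time variant.

The FPLR rules express every weight update as

    dw = eta(Ca) * (F(Ca) - w)            (1D rule)
    dw = eta(Ca, w) * (F(Ca, w) - w)      (2D rule)

where ``F`` gives the *fixed point* the weight is being driven toward and
``eta`` the rate at which it approaches it, both step functions of the
calcium concentration (and, in the 2D rule, of the current weight).  A
protein-gated rule dispatches between a 1D rule (no stabilizing protein:
weights drift back to a single baseline) and a 2D rule (protein present:
weights stabilize into one of several basins of attraction).

Units convention
----------------
Learning rates stored in rules and presets are *rates per time unit* (per
millisecond for the fast presets, per second for the late-phase preset).
The per-step learning fraction used by the discrete update is
``eta(Ca) * dt``, which must lie in [0, 1]; a per-step fraction of 1 makes
the weight jump to the fixed point in a single step.  With ``dt = 1`` the
rate and the per-step fraction coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "REGION_NAMES",
    "Thresholds",
    "StepFunction1D",
    "BasinSpec",
    "ScalarRegion",
    "FPLRRule1D",
    "FPLRRule2D",
    "ProteinGatedRule",
    "SBCParams",
    "GBParams",
    "WeightTrajectory",
    "classify_region",
    "classify_regions",
    "eval_step",
    "sbc_linear_delta",
    "sbc_decay_delta",
    "sbc_cadep_delta",
    "fplr1d_delta",
    "closed_form_weight",
    "gb_delta",
    "gb_simplified_delta",
    "efficacy_to_weight",
    "weight_to_efficacy",
    "lookup_2d",
    "fplr2d_delta",
    "protein_gated_delta",
    "validate_basins",
    "integrate_rule",
]

#: Region names for the canonical two-threshold rule, in ascending calcium
#: order: below theta_D, between the thresholds, and at or above theta_P.
REGION_NAMES = ("pre_depressive", "depressive", "potentiative")

#: Tolerance within which a weight is considered to sit exactly on a basin
#: boundary (treated as an unstable fixed point).
BOUNDARY_TOL = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """Calcium thresholds separating plasticity regions.

    ``theta_D`` and ``theta_P`` are the canonical depression and
    potentiation thresholds (arbitrary concentration units).  ``extra``
    holds any additional thresholds (e.g. a no-man's-land boundary between
    the depressive and potentiative regions, or a post-potentiative neutral
    zone above them); the merged list must be strictly increasing and
    positive.  Region boundaries are half-open: region ``i`` contains
    calcium in ``[theta_i, theta_{i+1})``.
    """

    theta_D: float
    theta_P: float
    extra: tuple = ()

    def __post_init__(self):
        merged = tuple(sorted((self.theta_D, self.theta_P) + tuple(self.extra)))
        if any(t <= 0 for t in merged):
            raise ValueError("all thresholds must be strictly positive")
        if any(b <= a for a, b in zip(merged, merged[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not self.theta_D < self.theta_P:
            raise ValueError("theta_D must be below theta_P")
        object.__setattr__(self, "extra", tuple(self.extra))

    @property
    def all_thresholds(self) -> tuple:
        """Full ascending threshold list (theta_D, theta_P and extras)."""
        return tuple(sorted((self.theta_D, self.theta_P) + self.extra))

    @property
    def n_regions(self) -> int:
        return len(self.all_thresholds) + 1


@dataclass(frozen=True)
class StepFunction1D:
    """Piecewise-constant (or sum-of-sigmoids) function of calcium.

    ``values`` has exactly one more entry than ``thresholds``; value ``i``
    applies on the half-open interval ``[thresholds[i-1], thresholds[i])``.
    When ``sharpness`` is given (one positive steepness ``b_i`` per
    threshold) the function is the smooth sum of sigmoids

        v_0 + sum_i (v_i - v_{i-1}) / (1 + exp(-b_i (ca - theta_i)))

    which converges to the hard step as every ``b_i -> inf``.
    """

    thresholds: tuple
    values: tuple
    sharpness: Optional[tuple] = None

    def __post_init__(self):
        thr = tuple(float(t) for t in self.thresholds)
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "values", vals)
        if len(vals) != len(thr) + 1:
            raise ValueError("values must be exactly one longer than thresholds")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.sharpness is not None:
            sh = tuple(float(b) for b in self.sharpness)
            if len(sh) != len(thr):
                raise ValueError("sharpness must have one entry per threshold")
            if any(b <= 0 for b in sh):
                raise ValueError("sharpness values must be positive")
            object.__setattr__(self, "sharpness", sh)

    @property
    def is_hard(self) -> bool:
        return self.sharpness is None

    def __call__(self, ca):
        ca = np.asarray(ca, dtype=float)
        if self.is_hard:
            idx = np.searchsorted(self.thresholds, ca, side="right")
            out = np.asarray(self.values, dtype=float)[idx]
        else:
            vals = self.values
            out = np.full_like(ca, vals[0], dtype=float)
            for i, (theta, b) in enumerate(zip(self.thresholds, self.sharpness)):
                out = out + (vals[i + 1] - vals[i]) * expit(b * (ca - theta))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BasinSpec:
    """Weight-dependent fixed points for one calcium region of a 2D rule.

    ``N`` stable fixed points partition the weight axis into ``N`` basins of
    attraction delimited by ``N + 1`` strictly increasing boundaries; each
    fixed point must lie strictly inside its basin so that basins never
    overlap.  Interior boundaries are unstable fixed points by default
    (``boundary_stability`` entry ``"unstable"``); half-stable boundaries
    attach to the lower (``"lower"``) or upper (``"upper"``) basin instead.
    """

    fixed_points: tuple
    boundaries: tuple
    learning_rates: tuple
    boundary_stability: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "fixed_points", tuple(float(v) for v in self.fixed_points))
        object.__setattr__(self, "boundaries", tuple(float(v) for v in self.boundaries))
        object.__setattr__(self, "learning_rates", tuple(float(v) for v in self.learning_rates))
        problems = validate_basins(self)
        if problems:
            raise ValueError("invalid BasinSpec: " + "; ".join(problems))

    @property
    def n_basins(self) -> int:
        return len(self.fixed_points)


def validate_basins(spec: "BasinSpec") -> list:
    """Return a list of human-readable invariant violations (empty = ok)."""
    problems = []
    fps, bnds, rates = spec.fixed_points, spec.boundaries, spec.learning_rates
    if len(bnds) != len(fps) + 1:
        problems.append(
            f"expected {len(fps) + 1} boundaries for {len(fps)} fixed points, got {len(bnds)}"
        )
    if any(b <= a for a, b in zip(bnds, bnds[1:])):
        problems.append(f"boundaries not strictly increasing: {list(bnds)}")
    else:
        for k, fp in enumerate(fps):
            if k + 1 < len(bnds) and not (bnds[k] < fp < bnds[k + 1]):
                problems.append(
                    f"fixed point {fp} outside its basin ({bnds[k]}, {bnds[k + 1]})"
                )
    if len(rates) != len(fps):
        problems.append("one learning rate required per fixed point")
    for r in rates:
        if not (0.0 <= r <= 1.0):
            problems.append(f"learning rate {r} outside [0, 1]")
    if spec.boundary_stability is not None:
        if len(spec.boundary_stability) != len(bnds):
            problems.append("boundary_stability must have one entry per boundary")
        for s in spec.boundary_stability:
            if s not in ("unstable", "lower", "upper"):
                problems.append(f"unknown boundary stability {s!r}")
    return problems


@dataclass(frozen=True)
class ScalarRegion:
    """Weight-independent (fixed point, learning rate) pair for one region."""

    F: float
    eta: float

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("learning rate must be non-negative")


@dataclass(frozen=True)
class FPLRRule1D:
    """One-dimensional FPLR rule: dw = eta(Ca) * (F(Ca) - w).

    ``F`` and ``eta`` are step functions built on the same thresholds as
    ``thresholds``; ``eta`` values are rates per time unit, and the per-step
    fraction ``eta * dt`` must not exceed 1 (values above 1 overshoot the
    fixed point and oscillate).
    """

    thresholds: Thresholds
    F: StepFunction1D
    eta: StepFunction1D
    dt: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for v in self.eta.values:
            if v < 0:
                raise ValueError("learning rates must be non-negative")
            if v * self.dt > 1.0 + 1e-12:
                raise ValueError(
                    f"per-step learning fraction eta*dt = {v * self.dt} exceeds 1"
                )


@dataclass(frozen=True)
class FPLRRule2D:
    """Two-dimensional FPLR rule: dw = eta(Ca, w) * (F(Ca, w) - w).

    One entry per calcium region: a :class:`ScalarRegion` for regions where
    the fixed point is weight-independent, or a :class:`BasinSpec` for
    regions (typically the pre-depressive one) with several weight basins.
    """

    thresholds: Thresholds
    regions: tuple
    dt: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        if len(self.regions) != self.thresholds.n_regions:
            raise ValueError(
                f"need {self.thresholds.n_regions} region entries, got {len(self.regions)}"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for entry in self.regions:
            if isinstance(entry, ScalarRegion):
                rates = (entry.eta,)
            elif isinstance(entry, BasinSpec):
                rates = entry.learning_rates
            else:
                raise TypeError("regions must be ScalarRegion or BasinSpec")
            for r in rates:
                if r * self.dt > 1.0 + 1e-12:
                    raise ValueError("per-step learning fraction eta*dt exceeds 1")


@dataclass(frozen=True)
class ProteinGatedRule:
    """Protein-synthesis-gated rule.

    With no stabilizing protein (``protein = 0``) the late phase follows a
    1D rule whose pre-depressive fixed point is a single baseline; with
    protein present (``protein = 1``) it follows a 2D rule whose
    pre-depressive basins stabilize potentiated and depressed weights at
    separate levels.  Both sub-rules must share calcium thresholds.
    """

    no_protein_rule: FPLRRule1D
    protein_rule: FPLRRule2D

    def __post_init__(self):
        a = self.no_protein_rule.thresholds.all_thresholds
        b = self.protein_rule.thresholds.all_thresholds
        if a != b:
            raise ValueError("sub-rules must share calcium thresholds")
        if self.no_protein_rule.dt != self.protein_rule.dt:
            raise ValueError("sub-rules must share dt")

    @property
    def dt(self) -> float:
        return self.no_protein_rule.dt

    @property
    def thresholds(self) -> Thresholds:
        return self.no_protein_rule.thresholds


@dataclass(frozen=True)
class SBCParams:
    """Parameters of the Shouval-Bear-Cooper rule family.

    ``k_D < 0`` and ``k_P > 0`` are the signed depression/potentiation rates
    of the two-threshold Omega function; ``lambda_decay >= 0`` adds weight
    decay (fixed points become k/lambda); ``eta`` is either a constant
    learning rate or a calcium-dependent (sigmoidal) step function.
    """

    thresholds: Thresholds
    k_D: float
    k_P: float
    lambda_decay: float = 0.0
    eta: Union[float, StepFunction1D] = 1.0
    omega_sharpness: Optional[tuple] = None

    def __post_init__(self):
        if not (self.k_D < 0 < self.k_P):
            raise ValueError("require k_D < 0 < k_P")
        if self.lambda_decay < 0:
            raise ValueError("lambda_decay must be non-negative")

    @property
    def omega(self) -> StepFunction1D:
        """The two-threshold plasticity function Omega(Ca)."""
        return StepFunction1D(
            thresholds=(self.thresholds.theta_D, self.thresholds.theta_P),
            values=(0.0, self.k_D, self.k_P),
            sharpness=self.omega_sharpness,
        )

    def eta_at(self, ca) -> float:
        return self.eta(ca) if callable(self.eta) else float(self.eta)


@dataclass(frozen=True)
class GBParams:
    """Parameters of the Graupner-Brunel bistable-efficacy rule.

    The efficacy drifts along the cubic ``-w (1 - w) (w_star - w)`` between
    a DOWN state at 0 and an UP state at 1, with depression/potentiation
    terms gated by the calcium thresholds.  ``w_UP``/``w_DOWN`` map the
    internal efficacy onto physical weights.  ``eta_drift`` is only used by
    the simplified variant.
    """

    thresholds: Thresholds
    w_star: float = 0.5
    eta_D: float = 1.0
    eta_P: float = 1.0
    tau: float = 1.0
    eta_drift: float = 0.0
    w_UP: float = 1.0
    w_DOWN: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.w_star < 1.0):
            raise ValueError("w_star must lie in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.eta_D < 0 or self.eta_P < 0 or self.eta_drift < 0:
            raise ValueError("rates must be non-negative")


def efficacy_to_weight(rho, params: GBParams):
    """Map GB efficacy in [0, 1] onto a physical weight."""
    return params.w_DOWN + np.asarray(rho) * (params.w_UP - params.w_DOWN)


def weight_to_efficacy(w, params: GBParams):
    return (np.asarray(w) - params.w_DOWN) / (params.w_UP - params.w_DOWN)


@dataclass
class WeightTrajectory:
    """Synaptic weight time series produced by integrating a rule."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def initial(self) -> float:
        return float(self.values[0])

    @property
    def final(self) -> float:
        return float(self.values[-1])

    @property
    def delta_w(self) -> float:
        return self.final - self.initial


# ---------------------------------------------------------------------------
# region classification and step evaluation
# ---------------------------------------------------------------------------

def classify_region(ca: float, thresholds: Thresholds):
    """Classify a calcium level into its plasticity region.

    Uses half-open intervals: region ``i`` is ``[theta_i, theta_{i+1})``.
    For the canonical two-threshold case the region *name* is returned
    (``"pre_depressive"``, ``"depressive"`` or ``"potentiative"``); with
    extra thresholds the integer region index is returned instead.
    """
    if ca < 0:
        raise ValueError("calcium concentration cannot be negative")
    idx = int(np.searchsorted(thresholds.all_thresholds, ca, side="right"))
    if not thresholds.extra:
        return REGION_NAMES[idx]
    return idx


def classify_regions(ca: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    """Vectorized region indices (0 = pre-depressive, ...) for a trace."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentration cannot be negative")
    return np.searchsorted(thresholds.all_thresholds, ca, side="right")


def eval_step(f: StepFunction1D, ca):
    """Evaluate a step function at a calcium level (hard or soft mode)."""
    if np.any(np.asarray(ca) < 0):
        raise ValueError("calcium concentration cannot be negative")
    return f(ca)


# ---------------------------------------------------------------------------
# per-step weight updates
# ---------------------------------------------------------------------------

def sbc_linear_delta(ca: float, params: SBCParams) -> float:
    """Linear SBC update: dw = eta * Omega(Ca); independent of w."""
    return params.eta_at(ca) * params.omega(ca)


def sbc_decay_delta(ca: float, w: float, params: SBCParams) -> float:
    """SBC update with weight decay: dw = eta * (Omega(Ca) - lambda w).

    With ``lambda_decay = 0`` this reduces silently to the linear rule.
    The per-region fixed points are 0, k_D/lambda and k_P/lambda.
    """
    return params.eta_at(ca) * (params.omega(ca) - params.lambda_decay * w)


def sbc_cadep_delta(ca: float, w: float, params: SBCParams) -> float:
    """SBC update with a calcium-dependent (sigmoidal) learning rate.

    Identical fixed points to :func:`sbc_decay_delta`; the approach rate
    scales with ``eta(Ca)``, so pre-depressive decay toward baseline is slow
    while plasticity at high calcium is fast.
    """
    return sbc_decay_delta(ca, w, params)


def fplr1d_delta(ca: float, w: float, rule: FPLRRule1D) -> float:
    """One step of the 1D FPLR rule: dw = eta(Ca) dt (F(Ca) - w)."""
    return rule.eta(ca) * rule.dt * (rule.F(ca) - w)


def closed_form_weight(w0: float, C: float, t_S: float, t_E: float,
                       rule: FPLRRule1D) -> float:
    """Weight at ``t_E`` under constant calcium ``C``, in closed form.

    The continuous-time limit of the 1D rule relaxes exponentially toward
    the fixed point:  w(t_E) = F(C) + (w(t_S) - F(C)) exp(-eta (t_E - t_S)).
    The continuous rate is taken as ``-ln(1 - eta dt) / dt`` so that the
    closed form agrees *exactly* with the discrete geometric relaxation at
    multiples of dt.  A per-step fraction of 1 jumps straight to F(C).
    """
    if t_E < t_S:
        raise ValueError("t_E must not precede t_S")
    F = rule.F(C)
    step = rule.eta(C) * rule.dt
    if step >= 1.0:
        return float(F) if t_E > t_S else float(w0)
    eta_cont = -math.log1p(-step) / rule.dt
    return float(F + (w0 - F) * math.exp(-eta_cont * (t_E - t_S)))


def gb_delta(ca: float, w: float, params: GBParams, dt: float = 1.0) -> float:
    """One step of the original GB rule (noise term omitted).

    The cubic drift term is always active; the depression term adds in the
    depressive *and* potentiative regions; the potentiation term only in
    the potentiative region.  Returns dw = dt/tau * (sum of active terms).
    """
    idx = classify_regions(np.asarray(ca), params.thresholds)
    total = -w * (1.0 - w) * (params.w_star - w)
    if idx >= 1:
        total -= params.eta_D * w
    if idx >= 2:
        total += params.eta_P * (1.0 - w)
    return dt * total / params.tau


def gb_simplified_delta(ca: float, w: float, params: GBParams,
                        dt: float = 1.0) -> float:
    """One step of the simplified GB rule: one process active at a time.

    Pre-depressive calcium: exponential drift toward 0 or 1 depending on
    which side of the unstable fixed point ``w_star`` the weight sits (no
    change exactly at ``w_star``).  Depressive calcium: asymptotic decay to
    0 at rate ``eta_D``.  Potentiative: asymptotic rise to 1 at ``eta_P``.
    """
    idx = classify_regions(np.asarray(ca), params.thresholds)
    if idx == 0:
        if w < params.w_star:
            return -dt * params.eta_drift * w
        if w > params.w_star:
            return dt * params.eta_drift * (1.0 - w)
        return 0.0
    if idx == 1:
        return -dt * params.eta_D * w
    return dt * params.eta_P * (1.0 - w)


def lookup_2d(ca: float, w: float, rule: FPLRRule2D):
    """Resolve the (fixed point, learning rate) pair of the 2D rule.

    Scalar regions return their constants.  Basin regions return the fixed
    point and rate of the basin containing ``w``; a weight sitting exactly
    on an interior basin boundary (within ``1e-12``) is returned its own
    value as fixed point, making the boundary an unstable fixed point
    (half-stable boundaries instead attach to one of the adjacent basins).
    """
    idx = classify_regions(np.asarray(ca), rule.thresholds)
    entry = rule.regions[int(idx)]
    if isinstance(entry, ScalarRegion):
        return entry.F, entry.eta
    bnds = entry.boundaries
    if w < bnds[0] - BOUNDARY_TOL or w > bnds[-1] + BOUNDARY_TOL:
        raise ValueError(
            f"weight {w} outside basin support [{bnds[0]}, {bnds[-1]}]"
        )
    stability = entry.boundary_stability or ("unstable",) * len(bnds)
    for j in range(1, len(bnds) - 1):  # interior boundaries
        if abs(w - bnds[j]) <= BOUNDARY_TOL:
            mode = stability[j]
            if mode == "unstable":
                return bnds[j], entry.learning_rates[j - 1]
            k = j - 1 if mode == "lower" else j
            return entry.fixed_points[k], entry.learning_rates[k]
    k = int(np.searchsorted(bnds, w, side="right")) - 1
    k = min(max(k, 0), entry.n_basins - 1)
    return entry.fixed_points[k], entry.learning_rates[k]


def fplr2d_delta(ca: float, w: float, rule: FPLRRule2D) -> float:
    """One step of the 2D FPLR rule: dw = eta(Ca, w) dt (F(Ca, w) - w)."""
    F, eta = lookup_2d(ca, w, rule)
    return eta * rule.dt * (F - w)


def protein_gated_delta(ca: float, w: float, protein: int,
                        rule: ProteinGatedRule) -> float:
    """Dispatch on protein state: 0 -> 1D sub-rule, 1 -> 2D sub-rule."""
    if protein not in (0, 1):
        raise ValueError("protein state must be 0 or 1")
    if protein == 0:
        return fplr1d_delta(ca, w, rule.no_protein_rule)
    return fplr2d_delta(ca, w, rule.protein_rule)


# ---------------------------------------------------------------------------
# trajectory integration
# ---------------------------------------------------------------------------

def _integrate_fplr1d_hard(ca: np.ndarray, w0: float, rule: FPLRRule1D) -> np.ndarray:
    """Exact segment-wise integration of a hard-threshold 1D FPLR rule.

    Within a run of samples sharing one calcium region, the discrete update
    is a geometric relaxation toward that region's fixed point,
    ``w_n - F = (1 - eta dt)^n (w_0 - F)``, evaluated in closed form per
    segment.  This is the fast path used by the stimulation protocols.
    """
    idx = classify_regions(ca, rule.thresholds)
    Fv = np.asarray(rule.F.values, dtype=float)
    ev = np.asarray(rule.eta.values, dtype=float) * rule.dt
    out = np.empty(ca.size, dtype=float)
    w = float(w0)
    # boundaries of constant-region runs
    change = np.flatnonzero(np.diff(idx)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [idx.size]))
    for s, e in zip(starts, ends):
        F, eta = Fv[idx[s]], ev[idx[s]]
        n = e - s
        if eta == 0.0:
            out[s:e] = w
        elif eta == 1.0:
            out[s:e] = F
            w = F
        else:
            out[s:e] = F + (w - F) * np.power(1.0 - eta, np.arange(1, n + 1))
            w = float(out[e - 1])
    return out


def integrate_rule(ca_trace, w0: float, rule, protein_trace=None) -> WeightTrajectory:
    """Integrate a plasticity rule against a calcium trace.

    ``ca_trace`` is any object with ``values`` (uniformly sampled calcium)
    and ``dt`` attributes, e.g. :class:`fplr.calcium.CalciumTrace`.  The
    rule may be an :class:`FPLRRule1D`, :class:`FPLRRule2D`,
    :class:`ProteinGatedRule` (requires ``protein_trace`` of the same
    length), :class:`SBCParams` or :class:`GBParams`.  The update applied
    at sample ``n`` uses the calcium at sample ``n``; the trajectory has the
    same length as the calcium trace and starts from the post-first-step
    weight unless the first step leaves it unchanged.
    """
    ca = np.asarray(ca_trace.values, dtype=float)
    dt = float(ca_trace.dt)
    if not np.isfinite(w0):
        raise ValueError("w0 must be finite")
    if isinstance(rule, ProteinGatedRule):
        if protein_trace is None:
            raise ValueError("protein_trace required for a protein-gated rule")
        protein = np.asarray(protein_trace)
        if protein.shape != ca.shape:
            raise ValueError("protein trace length must match calcium trace")
    elif protein_trace is not None:
        raise ValueError("protein_trace only applies to protein-gated rules")

    if isinstance(rule, FPLRRule1D) and rule.F.is_hard and rule.eta.is_hard:
        return WeightTrajectory(_integrate_fplr1d_hard(ca, w0, rule), dt)

    w = float(w0)
    out = np.empty(ca.size, dtype=float)
    for n in range(ca.size):
        c = ca[n]
        if isinstance(rule, FPLRRule1D):
            w += fplr1d_delta(c, w, rule)
        elif isinstance(rule, FPLRRule2D):
            w += fplr2d_delta(c, w, rule)
        elif isinstance(rule, ProteinGatedRule):
            w += protein_gated_delta(c, w, int(protein[n]), rule)
        elif isinstance(rule, SBCParams):
            w += sbc_decay_delta(c, w, rule) * dt
        elif isinstance(rule, GBParams):
            w += gb_delta(c, w, rule, dt=dt)
        else:
            raise TypeError(f"unsupported rule type {type(rule).__name__}")
        out[n] = w
    return WeightTrajectory(out, dt)
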