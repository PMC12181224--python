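"""Shipped rule presets and their JSON serialization.

Four presets are bundled with the package:

``frequency``
    Early-phase 1D FPLR rule plus spike-calcium parameters for
    frequency-dependent plasticity (pre-depressive drift off).
``stdp``
    Same rule shape with the spike-timing calibration (small rates, so a
    single pre/post pairing moves the weight only slightly).
``btsp``
    Behavioral-timescale plasticity: slow calcium (tau_Ca = 2 s), the
    leaky-integrator neuron, and the circular-track input configuration.
``late_phase_fig5``
    Protein-gated late-phase rule on a seconds time base: early plasticity
    jumps to the early fixed points (42% / 225% of baseline), then
    hours-long drift either back to baseline (no protein) or into
    stabilized basins at 61% / 142% of baseline (protein present).

User presets are ordinary JSON files with the same schema and can be
loaded by path.  Learning rates are rates per the preset's declared time
unit; the per-step fraction is ``eta * dt`` and is validated to be <= 1 at
load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .calcium import CalciumParams
from .rules import (
    BasinSpec,
    FPLRRule1D,
    FPLRRule2D,
    ProteinGatedRule,
    ScalarRegion,
    StepFunction1D,
    Thresholds,
)

__all__ = ["Preset", "BUILTIN_PRESETS", "load_preset", "save_preset"]

BUILTIN_PRESETS = ("frequency", "stdp", "btsp", "late_phase_fig5")


class PresetError(ValueError):
    """Raised when a preset document is unknown or fails validation."""


@dataclass
class Preset:
    """A named, validated parameter set.

    ``rule`` is the constructed plasticity rule (:class:`FPLRRule1D` or
    :class:`ProteinGatedRule`); ``calcium`` holds spike-calcium parameters
    where applicable; ``raw`` keeps the verbatim document for round-trips
    and provenance.
    """

    name: str
    rule: Union[FPLRRule1D, ProteinGatedRule]
    dt: float
    time_unit: str
    provenance: str
    calcium: Optional[CalciumParams] = None
    raw: dict = None

    @property
    def thresholds(self) -> Thresholds:
        return self.rule.thresholds

    @property
    def w0(self) -> float:
        return float(self.raw.get("w0", 1.0))

    def to_dict(self) -> dict:
        return dict(self.raw)


def _require(doc: dict, key: str, name: str):
    if key not in doc:
        raise PresetError(f"preset {name!r}: missing required field {key!r}")
    return doc[key]


def _build_thresholds(doc: dict, name: str) -> Thresholds:
    t = _require(doc, "thresholds", name)
    extra = tuple(t.get("extra", ()))
    return Thresholds(float(t["theta_D"]), float(t["theta_P"]), extra)


def _build_1d(doc: dict, name: str) -> FPLRRule1D:
    thr = _build_thresholds(doc, name)
    fps = _require(doc, "fixed_points", name)
    rates = _require(doc, "learning_rates", name)
    dt = float(_require(doc, "dt", name))
    sharp = doc.get("sharpness")
    sharp = tuple(sharp) if sharp is not None else None
    try:
        return FPLRRule1D(
            thresholds=thr,
            F=StepFunction1D(thr.all_thresholds, tuple(fps), sharp),
            eta=StepFunction1D(thr.all_thresholds, tuple(rates), sharp),
            dt=dt,
        )
    except (ValueError, TypeError) as exc:
        raise PresetError(f"preset {name!r}: {exc}") from exc


def _build_protein_gated(doc: dict, name: str) -> ProteinGatedRule:
    thr = _build_thresholds(doc, name)
    dt = float(_require(doc, "dt", name))
    np_doc = _require(doc, "no_protein", name)
    p_doc = _require(doc, "protein", name)
    try:
        no_protein = FPLRRule1D(
            thresholds=thr,
            F=StepFunction1D(thr.all_thresholds, tuple(np_doc["fixed_points"])),
            eta=StepFunction1D(thr.all_thresholds, tuple(np_doc["learning_rates"])),
            dt=dt,
        )
        basins = p_doc["pre_depressive_basins"]
        protein = FPLRRule2D(
            thresholds=thr,
            regions=(
                BasinSpec(
                    fixed_points=tuple(basins["fixed_points"]),
                    boundaries=tuple(basins["boundaries"]),
                    learning_rates=tuple(basins["learning_rates"]),
                ),
                ScalarRegion(float(p_doc["depressive"]["F"]),
                             float(p_doc["depressive"]["eta"])),
                ScalarRegion(float(p_doc["potentiative"]["F"]),
                             float(p_doc["potentiative"]["eta"])),
            ),
            dt=dt,
        )
        return ProteinGatedRule(no_protein_rule=no_protein, protein_rule=protein)
    except (KeyError, ValueError, TypeError) as exc:
        raise PresetError(f"preset {name!r}: {exc}") from exc


def _build_preset(doc: dict, name: str) -> Preset:
    kind = doc.get("kind", "fplr1d")
    if kind == "fplr1d":
        rule = _build_1d(doc, name)
    elif kind == "protein_gated":
        rule = _build_protein_gated(doc, name)
    else:
        raise PresetError(f"preset {name!r}: unknown kind {kind!r}")
    calcium = None
    if "calcium" in doc:
        c = doc["calcium"]
        calcium = CalciumParams(float(c["C_pre"]), float(c.get("C_post", 0.0)),
                                float(c["tau_Ca"]))
    return Preset(
        name=doc.get("name", name),
        rule=rule,
        dt=float(doc["dt"]),
        time_unit=doc.get("time_unit", "ms"),
        provenance=doc.get("provenance", ""),
        calcium=calcium,
        raw=doc,
    )


def load_preset(name_or_path: Union[str, Path]) -> Preset:
    """Load a built-in preset by name or a user preset by file path.

    Raises :class:`PresetError` with a descriptive message for unknown
    names, schema violations, or learning fractions exceeding 1.
    """
    name = str(name_or_path)
    if name in BUILTIN_PRESETS:
        text = resources.files("fplr").joinpath("data", f"{name}.json").read_text()
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise PresetError(
                f"unknown preset {name!r}: not one of {BUILTIN_PRESETS} "
                "and no such file"
            )
        text = path.read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PresetError(f"preset {name!r}: invalid JSON ({exc})") from exc
    return _build_preset(doc, name)


def save_preset(preset: Preset, path: Union[str, Path]) -> Path:
    """Write a preset's document back to JSON (lossless round-trip)."""
    path = Path(path)
    path.write_text(json.dumps(preset.raw, indent=2) + "\n")
    return path
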