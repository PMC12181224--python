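"""Trace and result serialization plus run manifests.

Traces are two-column CSV files with a header row -- ``time,calcium`` or
``time,weight`` -- times in the trace's own units (milliseconds for the
fast presets), '.' decimal, full double precision.  A protocol run writes
its calcium and weight traces, a bar-code JSON, a summary JSON and a run
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .calcium import CalciumTrace
from .rules import WeightTrajectory

__all__ = [
    "RunManifest",
    "read_trace_csv",
    "write_trace_csv",
    "write_result",
]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: preset, overrides, seed."""

    preset: str
    command: str = ""
    overrides: dict = field(default_factory=dict)
    seed: Optional[int] = None
    version: str = __version__
    python: str = platform.python_version()
    outputs: list = field(default_factory=list)

    def write(self, out_dir: Union[str, Path]) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def write_trace_csv(path: Union[str, Path], times: np.ndarray,
                    values: np.ndarray, value_name: str = "calcium") -> Path:
    """Write a (time, value) series as CSV with full double precision."""
    path = Path(path)
    df = pd.DataFrame({"time": np.asarray(times), value_name: np.asarray(values)})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trace_csv(path: Union[str, Path]):
    """Read a two-column (time, value) CSV; returns (times, values)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_result(result, out_dir: Union[str, Path],
                 manifest: Optional[RunManifest] = None) -> dict:
    """Write a ProtocolResult to a directory; returns the file map.

    Produces ``calcium.csv``, ``weights.csv``, ``barcode.json`` and
    ``summary.json`` (plus ``manifest.json`` when a manifest is given,
    written first).  A written-then-reloaded trace equals the in-memory
    one exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    if manifest is not None:
        files["manifest"] = manifest.write(out)
    ca: CalciumTrace = result.calcium
    wt: WeightTrajectory = result.weights
    files["calcium"] = write_trace_csv(out / "calcium.csv", ca.times, ca.values,
                                       "calcium")
    files["weights"] = write_trace_csv(out / "weights.csv", wt.times, wt.values,
                                       "weight")
    (out / "barcode.json").write_text(
        json.dumps(result.barcode.to_dict(), indent=2, default=_json_default) + "\n")
    files["barcode"] = out / "barcode.json"
    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=2, default=_json_default) + "\n")
    files["summary"] = out / "summary.json"
    if manifest is not None:
        manifest.outputs = [str(p) for p in files.values()]
        manifest.write(out)
    return files
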