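"""Flat-file formats: trial tables, physiological traces, configs, results.

- Trial tables: CSV, one row per trial, booleans as 0/1, times in ms.
- Traces: two-column CSV (time_s, value) plus a JSON sidecar carrying the
  channel name, sample rate, and event list (a BIDS-physio-like layout).
- Configs: YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from threatdetect.physio_sim import PhysioTrace
from threatdetect.schedule import BOOL_COLUMNS


def save_trials(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = trials.copy()
    for col in BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
    return path


def load_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    for col in BOOL_COLUMNS:
        if col in trials.columns:
            trials[col] = trials[col].astype(bool)
    return trials


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def save_trace(trace: PhysioTrace, csv_path) -> Path:
    csv_path = Path(csv_path)
    frame = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = {
        "channel": trace.channel,
        "sample_rate_hz": trace.sample_rate_hz,
        "t0": trace.t0,
        "events": [[float(t), str(label)] for t, label in trace.events],
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def load_trace(csv_path) -> PhysioTrace:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    meta = json.loads(_sidecar_path(csv_path).read_text())
    return PhysioTrace(
        channel=meta["channel"],
        sample_rate_hz=float(meta["sample_rate_hz"]),
        samples=frame["value"].to_numpy(),
        t0=float(meta["t0"]),
        events=[(float(t), str(label)) for t, label in meta["events"]],
    )


def save_yaml(data: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_plain(data), sort_keys=True))
    return path


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
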