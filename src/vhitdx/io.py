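"""Plain-CSV persistence for traces, manifests and derived tables.

Trace files carry the header ``time_ms,head_vel_dps,eye_vel_dps`` (one row
per sample); the manifest holds one row per trial with its ground truth.
Every file written by the pipeline starts with a ``# config_hash=...``
comment line so outputs are traceable to the resolved configuration.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import TraceError, VelocityTrace

TRACE_HEADER = "time_ms,head_vel_dps,eye_vel_dps"


def config_hash(config: dict) -> str:
    """Short stable hash of a resolved configuration dictionary."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _hash_line(h: str) -> str:
    return f"# config_hash={h or 'unset'}\n"


def write_trace_csv(trace: VelocityTrace, path: str | Path, config_hash: str = "") -> None:
    with open(path, "w") as f:
        f.write(_hash_line(config_hash))
        f.write(TRACE_HEADER + "\n")
        for t, h, e in zip(trace.time, trace.head_vel, trace.eye_vel):
            f.write(f"{t:.6g},{h:.6g},{e:.6g}\n")


def read_trace_csv(path: str | Path, **trace_kw) -> VelocityTrace:
    """Read one trial trace; malformed files raise :class:`TraceError`."""
    try:
        df = pd.read_csv(path, comment="#")
        return VelocityTrace(df["time_ms"].to_numpy(float),
                             df["head_vel_dps"].to_numpy(float),
                             df["eye_vel_dps"].to_numpy(float), **trace_kw)
    except TraceError:
        raise
    except Exception as exc:
        raise TraceError(f"unreadable trace file {path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    with open(path, "w") as f:
        f.write(_hash_line(config_hash))
        df.to_csv(f, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj, path: str | Path, config_hash: str = "") -> None:
    payload = {"config_hash": config_hash or "unset", **obj}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")


def write_dataset(dataset, out_dir: str | Path, config_hash: str = "") -> Path:
    """Write one CSV per trial plus ``manifest.csv`` under `out_dir`."""
    out = Path(out_dir)
    traces_dir = out / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    for trace in dataset.traces:
        write_trace_csv(trace, traces_dir / f"{trace.trial_id}.csv", config_hash)
    write_table(dataset.manifest, out / "manifest.csv", config_hash)
    return out


def read_manifest(dataset_dir: str | Path) -> pd.DataFrame:
    path = Path(dataset_dir) / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no manifest at {path}")
    return read_table(path)
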