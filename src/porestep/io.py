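"""Trace, table and result file formats.

Traces are stored as raw little-endian float32 samples (pA) next to a
JSON metadata sidecar holding every acquisition parameter, the seed and a
schema version, or alternatively as a two-column TSV ``(time_s,
current_pa)`` for interoperability.  Ground truth, event tables and level
tables are TSV with a header row; scalar results are JSON.  Everything is
plain text or raw floats — diffable and language-agnostic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import EventPlan, LevelSpec, PlacedEvent, TraceParams, TraceRecord

__all__ = [
    "SCHEMA_VERSION",
    "write_trace",
    "read_trace",
    "write_trace_tsv",
    "read_trace_tsv",
    "write_ground_truth",
    "write_table",
    "write_json",
]

SCHEMA_VERSION = 1


def _sidecar_path(prefix: str | Path) -> Path:
    return Path(str(prefix) + ".json")


def _samples_path(prefix: str | Path) -> Path:
    return Path(str(prefix) + ".dat")


def write_trace(record: TraceRecord, prefix: str | Path) -> None:
    """Write raw float32 samples plus a JSON metadata sidecar."""
    samples = np.asarray(record.samples, dtype="<f4")
    _samples_path(prefix).write_bytes(samples.tobytes())
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_samples": int(len(samples)),
        "rng_seed": record.rng_seed,
        "params": dataclasses.asdict(record.params),
    }
    _sidecar_path(prefix).write_text(json.dumps(meta, indent=2) + "\n")


def read_trace(prefix: str | Path) -> TraceRecord:
    """Read a trace written by :func:`write_trace`; validates the sidecar."""
    sidecar = _sidecar_path(prefix)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unknown schema version {meta.get('schema_version')!r}")
    samples = np.frombuffer(_samples_path(prefix).read_bytes(), dtype="<f4").astype(float)
    if len(samples) != meta["n_samples"]:
        raise ValueError(
            f"sample-count mismatch: sidecar says {meta['n_samples']}, file has {len(samples)}"
        )
    params = TraceParams(**meta["params"])
    return TraceRecord(samples=samples, params=params, rng_seed=meta.get("rng_seed"))


def write_trace_tsv(record: TraceRecord, path: str | Path) -> None:
    """Two-column TSV dialect: time_s, current_pa."""
    fs = record.params.sampling_rate_hz
    t = np.arange(len(record.samples)) / fs
    pd.DataFrame({"time_s": t, "current_pa": record.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.7g"
    )


def read_trace_tsv(path: str | Path, params: TraceParams | None = None) -> TraceRecord:
    """Read a two-column TSV trace; sampling rate inferred from time steps."""
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy(float)
    y = df["current_pa"].to_numpy(float)
    if params is None:
        dt = float(np.median(np.diff(t)))
        params = TraceParams(
            sampling_rate_hz=1.0 / dt,
            filter_cutoff_hz=None,
            noise_sd_pa=0.0,
            duration_s=len(y) * dt,
        )
    return TraceRecord(samples=y, params=params)


def write_ground_truth(events: list[PlacedEvent], fs: float, path: str | Path) -> None:
    """Ground-truth TSV: event_index, label, ordinal, start_s, end_s, current."""
    rows = []
    for i, ev in enumerate(events):
        for (ordinal, a, b), lv in zip(ev.level_spans, ev.plan.levels):
            rows.append(
                {
                    "event_index": i,
                    "construct_label": ev.plan.construct_label,
                    "ordinal": ordinal,
                    "start_s": a / fs,
                    "end_s": b / fs,
                    "level_current_pa": lv.current_pa,
                    "gdnhcl_mode": ev.plan.gdnhcl_mode,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
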