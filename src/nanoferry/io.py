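"""CSV dialect for velocity/force trace records.

Columns (header mandatory): time_s, velocity_A_per_ps, force_N.
Provenance metadata travels in a sidecar manifest JSON when traces are
written in bulk (see :func:`write_trace_dir`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .membrane_tf import TraceRecord

TRACE_COLUMNS = ("time_s", "velocity_A_per_ps", "force_N")


def write_trace_csv(record: TraceRecord, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": record.t, "velocity_A_per_ps": record.u, "force_N": record.y}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path: str | Path) -> TraceRecord:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns {sorted(missing)}")
    return TraceRecord(
        t=df["time_s"].to_numpy(),
        u=df["velocity_A_per_ps"].to_numpy(),
        y=df["force_N"].to_numpy(),
        meta={"source": str(path)},
    )


def write_trace_dir(records: Iterable[TraceRecord], out_dir: str | Path,
                    manifest_extra: dict | None = None) -> list[Path]:
    """Write records as trace_000.csv, ... plus a manifest.json with metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    entries = []
    for i, rec in enumerate(records):
        p = out / f"trace_{i:03d}.csv"
        write_trace_csv(rec, p)
        paths.append(p)
        entries.append({"file": p.name, "meta": _jsonable(rec.meta)})
    manifest = {"records": entries}
    if manifest_extra:
        manifest.update(_jsonable(manifest_extra))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def read_trace_dir(in_dir: str | Path) -> list[TraceRecord]:
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("trace_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trace_*.csv files under {in_dir}")
    return [read_trace_csv(p) for p in paths]


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-serializable form."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj
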