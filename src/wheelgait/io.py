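"""Delimited-text and JSON-sidecar persistence for records and traces.

Wheel telemetry is small (5-s blocks of 9 channels at 3 kHz), so everything
is stored as diffable CSV with a JSON sidecar carrying the sample rate,
geometry and provenance; no binary container is used.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gaits import GaitTimings, LIMBS
from .reconstruct import ForceTrace
from .simulate import VoltageRecord

__all__ = [
    "write_record",
    "read_record",
    "write_trace",
    "read_trace",
    "read_annotations",
    "timings_from_annotations",
]


def _sidecar(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_record(record: VoltageRecord, path: str | Path) -> None:
    """Write a VoltageRecord as CSV (t, s0..s8) plus a JSON sidecar."""
    path = Path(path)
    n_sensors = record.channels.shape[0]
    df = pd.DataFrame({"t": record.time})
    for k in range(n_sensors):
        df[f"s{k}"] = record.channels[k]
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {"sample_rate": record.sample_rate, "t0": record.t0, "n_sensors": n_sensors}
    gt = record.ground_truth
    if gt is not None:
        meta["ground_truth_summary"] = {
            "seed": gt.get("seed"),
            "stride_period": gt.get("stride_period"),
            "category": gt.get("category"),
            "mean_linear_speed": float(np.mean(gt["linear_speed"]))
            if "linear_speed" in gt
            else None,
        }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_record(path: str | Path) -> VoltageRecord:
    """Read a VoltageRecord written by :func:`write_record`."""
    path = Path(path)
    df = pd.read_csv(path)
    sensor_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    if not sensor_cols or "t" not in df.columns:
        raise ValueError(f"{path}: expected a 't' column and s0..sN channel columns")
    sensor_cols = sorted(sensor_cols, key=lambda c: int(c[1:]))
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta["sample_rate"])
        t0 = float(meta.get("t0", df["t"].iloc[0]))
    else:
        dt = float(np.median(np.diff(df["t"].to_numpy())))
        fs, t0 = 1.0 / dt, float(df["t"].iloc[0])
    return VoltageRecord(
        sample_rate=fs,
        channels=df[sensor_cols].to_numpy().T,
        t0=t0,
    )


def write_trace(trace: ForceTrace, path: str | Path) -> None:
    """Write a ForceTrace as CSV with columns t, force, stage."""
    pd.DataFrame(
        {"t": trace.time, "force": trace.force, "stage": trace.stage}
    ).to_csv(path, index=False, float_format="%.8g")


def read_trace(path: str | Path, sample_rate: float | None = None) -> ForceTrace:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return ForceTrace(
        time=t,
        force=df["force"].to_numpy(dtype=float),
        stage=str(df["stage"].iloc[0]),
        sample_rate=sample_rate,
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a footfall-annotation table (limb, onset_s, offset_s, stride_id)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"limb", "onset_s", "offset_s", "stride_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return df


def timings_from_annotations(df: pd.DataFrame) -> dict[int, GaitTimings]:
    """Per-stride GaitTimings from a footfall annotation table.

    The stride period is taken from the span of hind-limb onsets of
    consecutive strides where available, otherwise from onset-to-offset
    extent; phases are anchored at the first hind contact of each stride.
    """
    out: dict[int, GaitTimings] = {}
    stride_ids = sorted(df["stride_id"].unique())
    for i, sid in enumerate(stride_ids):
        sub = df[df["stride_id"] == sid]
        if set(sub["limb"]) != set(LIMBS):
            raise ValueError(f"stride {sid}: needs one row per limb {LIMBS}")
        onsets = {r.limb: float(r.onset_s) for r in sub.itertuples()}
        offsets = {r.limb: float(r.offset_s) for r in sub.itertuples()}
        anchor_limb = min(("LH", "RH"), key=lambda m: onsets[m])
        if i + 1 < len(stride_ids):
            nxt = df[df["stride_id"] == stride_ids[i + 1]]
            nxt_on = {r.limb: float(r.onset_s) for r in nxt.itertuples()}
            period = nxt_on[anchor_limb] - onsets[anchor_limb]
        else:
            period = max(offsets.values()) - min(onsets.values())
        if period <= 0:
            raise ValueError(f"stride {sid}: non-positive stride period")
        t0 = onsets[anchor_limb]
        out[sid] = GaitTimings(
            contact_onset={
                m: ((onsets[m] - t0) / period) % 1.0 for m in LIMBS
            },
            stance_fraction={
                m: min(max((offsets[m] - onsets[m]) / period, 1e-6), 1 - 1e-6)
                for m in LIMBS
            },
            stride_period=period,
        )
    return out
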