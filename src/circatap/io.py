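"""CSV dialects for logger exports and diaries.

Three plain-text dialects are supported, matching typical wearable-logger
exports:

* temperature: ``timestamp,temp_c`` at the native 10-min step;
* accelerometer: ``timestamp,x,y,z`` (units of g) at the 30-s step;
* diary: ``subject_id,rest_onset,rest_offset``.

Timestamps are ISO-8601 local time and taken at face value.  Lines starting
with ``#`` are comments.  Writers emit floats with ``repr`` so that
``read(write(x))`` reproduces the values bit-exactly.
"""

from __future__ import annotations

from collections import defaultdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .series import DiarySeries, EquispacedSeries

__all__ = [
    "read_temperature_csv", "write_temperature_csv",
    "read_accel_csv", "write_accel_csv",
    "read_diary_csv", "write_diary_csv",
    "read_series_csv", "write_series_csv",
]


def _fmt(v: float) -> str:
    return "nan" if np.isnan(v) else repr(float(v))


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _infer_series(ts: pd.DatetimeIndex, values: np.ndarray, label: str) -> EquispacedSeries:
    if len(ts) < 2:
        raise ValueError("need at least two rows to infer the sampling step")
    steps = np.diff(ts.asi8) / 1e9
    if not np.allclose(steps, steps[0]):
        raise ValueError("timestamps are not equispaced")
    return EquispacedSeries(ts[0].to_pydatetime(), float(steps[0]),
                            np.asarray(values, dtype=float), label)


# -- temperature -------------------------------------------------------------

def read_temperature_csv(path: str | Path) -> EquispacedSeries:
    df = _read_table(path, ["timestamp", "temp_c"])
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    return _infer_series(ts, df["temp_c"].to_numpy(), "wrist temperature (degC)")


def write_temperature_csv(series: EquispacedSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {series.label}\n" if series.label else "#\n")
        fh.write("timestamp,temp_c\n")
        for t, v in zip(series.timestamps(), series.values):
            fh.write(f"{t.isoformat()},{_fmt(v)}\n")


# -- accelerometer -----------------------------------------------------------

def read_accel_csv(path: str | Path) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Return (timestamps, Nx3 array of x/y/z readings in g)."""
    df = _read_table(path, ["timestamp", "x", "y", "z"])
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    return ts, df[["x", "y", "z"]].to_numpy(dtype=float)


def write_accel_csv(timestamps: pd.DatetimeIndex, xyz: np.ndarray, path: str | Path) -> None:
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape != (len(timestamps), 3):
        raise ValueError(f"xyz must be ({len(timestamps)}, 3), got {xyz.shape}")
    with open(path, "w") as fh:
        fh.write("timestamp,x,y,z\n")
        for t, row in zip(timestamps, xyz):
            fh.write(f"{t.isoformat()},{_fmt(row[0])},{_fmt(row[1])},{_fmt(row[2])}\n")


# -- diary -------------------------------------------------------------------

def read_diary_csv(path: str | Path) -> dict[str, DiarySeries]:
    """Read rest diaries; returns ``{subject_id: DiarySeries}``."""
    df = _read_table(path, ["subject_id", "rest_onset", "rest_offset"])
    by_subject: dict[str, list[tuple[datetime, datetime]]] = defaultdict(list)
    for row in df.itertuples(index=False):
        by_subject[str(row.subject_id)].append(
            (pd.Timestamp(row.rest_onset).to_pydatetime(),
             pd.Timestamp(row.rest_offset).to_pydatetime()))
    return {sid: DiarySeries(sorted(iv), subject_id=sid) for sid, iv in by_subject.items()}


def write_diary_csv(diaries: dict[str, DiarySeries] | DiarySeries, path: str | Path) -> None:
    if isinstance(diaries, DiarySeries):
        diaries = {diaries.subject_id: diaries}
    with open(path, "w") as fh:
        fh.write("subject_id,rest_onset,rest_offset\n")
        for sid, diary in diaries.items():
            for onset, offset in diary.intervals:
                fh.write(f"{sid},{onset.isoformat()},{offset.isoformat()}\n")


# -- generic single-channel series (derived A/P exports) ---------------------

def read_series_csv(path: str | Path, label: str = "") -> EquispacedSeries:
    df = _read_table(path, ["timestamp", "value"])
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    return _infer_series(ts, df["value"].to_numpy(), label)


def write_series_csv(series: EquispacedSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {series.label}\n" if series.label else "#\n")
        fh.write("timestamp,value\n")
        for t, v in zip(series.timestamps(), series.values):
            fh.write(f"{t.isoformat()},{_fmt(v)}\n")
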