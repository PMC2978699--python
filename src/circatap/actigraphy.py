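"""Derivation of motor activity (A) and body position (P) from a 3-axis
arm-worn accelerometer sampled every 30 s.

The logger is worn on the upper arm with its X-axis parallel to the
humerus, so gravity tilt encodes posture: P is the unsigned elevation of
the device X-axis over the horizontal plane (0 deg lying, 90 deg upright).
Motor activity is the angular displacement of the orientation vector
between consecutive 30-s readings; summing it over 10-min epochs gives the
total angular path travelled, later expressed in degrees per minute.

Static gravity is assumed to dominate each 30-s reading (tilt
interpretation); no separation of gravity from linear acceleration is
attempted.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd

from .series import EquispacedSeries

__all__ = [
    "motor_activity",
    "body_position",
    "motor_activity_series",
    "body_position_series",
    "derive_channels",
]

_ACCEL_STEP = 30.0  # seconds between static readings


def _angles_between(prev: np.ndarray, curr: np.ndarray) -> np.ndarray:
    """Angle in degrees between rows of two (N, 3) orientation arrays.

    Zero-magnitude vectors yield NaN (the reading carries no orientation).
    """
    np_prev = np.linalg.norm(prev, axis=-1)
    np_curr = np.linalg.norm(curr, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", prev, curr) / (np_prev * np_curr)
    cosang = np.where((np_prev == 0) | (np_curr == 0), np.nan, cosang)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def motor_activity(prev, curr) -> float:
    """Angular displacement (degrees, in [0, 180]) between two readings.

    Symmetric in its arguments and invariant to rescaling of either
    vector; identical orientations give 0.
    """
    return float(_angles_between(np.asarray(prev, float), np.asarray(curr, float)))


def body_position(sample) -> float:
    """Tilt of the device X-axis over the horizontal plane, degrees in [0, 90].

    ``arcsin(|x| / ||(x, y, z)||)``: 0 for a horizontal X-axis (subject
    lying), 90 for a vertical one (upright).  The unsigned x-component
    makes arm-down and arm-up both read vertical.
    """
    v = np.asarray(sample, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        return float("nan")
    return float(np.degrees(np.arcsin(abs(v[0]) / norm)))


def motor_activity_series(timestamps: pd.DatetimeIndex, xyz: np.ndarray,
                          label: str = "motor activity (deg/30s)") -> EquispacedSeries:
    """Per-step angular displacement series from raw 30-s x/y/z readings.

    The first sample has no predecessor and is set to 0 so the first
    10-min epoch stays defined.
    """
    xyz = np.asarray(xyz, dtype=float)
    out = np.empty(len(xyz))
    out[0] = 0.0
    out[1:] = _angles_between(xyz[:-1], xyz[1:])
    return _wrap(timestamps, out, label)


def body_position_series(timestamps: pd.DatetimeIndex, xyz: np.ndarray,
                         label: str = "body position (deg)") -> EquispacedSeries:
    xyz = np.asarray(xyz, dtype=float)
    norm = np.linalg.norm(xyz, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.degrees(np.arcsin(np.abs(xyz[:, 0]) / norm))
    p[norm == 0] = np.nan
    return _wrap(timestamps, p, label)


def derive_channels(timestamps: pd.DatetimeIndex,
                    xyz: np.ndarray) -> tuple[EquispacedSeries, EquispacedSeries]:
    """Derive (activity, position) 30-s series from one accelerometer export."""
    return (motor_activity_series(timestamps, xyz),
            body_position_series(timestamps, xyz))


def _wrap(timestamps: pd.DatetimeIndex, values: np.ndarray, label: str) -> EquispacedSeries:
    if len(timestamps) != len(values):
        raise ValueError("timestamps and samples differ in length")
    if len(timestamps) > 1:
        steps = np.diff(timestamps.asi8) / 1e9
        if not np.allclose(steps, steps[0]):
            raise ValueError("accelerometer timestamps are not equispaced")
        step = float(steps[0])
    else:
        step = _ACCEL_STEP
    start: datetime = timestamps[0].to_pydatetime()
    return EquispacedSeries(start, step, values, label)
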