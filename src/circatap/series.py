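"""Equispaced physiological time series: containers, artifact filtering,
epoch resampling, percentile normalization and sleep-diary binarization.

The unit of analysis throughout the package is a regularly sampled scalar
series (:class:`EquispacedSeries`).  Missing samples are carried as NaN so
that index arithmetic (time-of-day binning, day reshaping) stays valid;
they are never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EquispacedSeries",
    "DiarySeries",
    "SubjectRecording",
    "ArtifactRule",
    "TEMPERATURE_ARTIFACT_RULE",
    "filter_artifacts",
    "resample",
    "resample_to_10min",
    "activity_per_minute",
    "normalize_percentile",
    "diary_to_binary",
]

EPOCH_10MIN = 600.0  # seconds; the common grid of the fused recording


@dataclass
class EquispacedSeries:
    """A regularly sampled scalar time series.

    Parameters
    ----------
    start_time
        Wall-clock timestamp of the first sample (naive; timestamps are
        taken at face value, no time-zone handling).
    step
        Sampling interval in seconds, constant by construction.
    values
        Sample values; NaN marks a missing/rejected sample.
    label
        Free-text channel description, e.g. ``"wrist temperature (degC)"``.
    """

    start_time: datetime
    step: float
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")

    def __len__(self) -> int:
        return self.values.size

    def timestamps(self) -> pd.DatetimeIndex:
        """Implied sample timestamps ``start_time + i*step``."""
        return pd.date_range(self.start_time, periods=len(self),
                             freq=pd.Timedelta(seconds=self.step))

    def with_values(self, values: np.ndarray, label: str | None = None) -> "EquispacedSeries":
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def same_grid(self, other: "EquispacedSeries") -> bool:
        return (self.start_time == other.start_time
                and self.step == other.step
                and len(self) == len(other))


@dataclass
class DiarySeries:
    """Self-reported rest intervals for one subject.

    Intervals are ``(rest_onset, rest_offset)`` pairs, chronologically
    ordered and non-overlapping, with ``rest_offset > rest_onset``.
    """

    intervals: list[tuple[datetime, datetime]]
    subject_id: str = ""

    def __post_init__(self) -> None:
        prev_end = None
        for onset, offset in self.intervals:
            if offset <= onset:
                raise ValueError(
                    f"diary {self.subject_id!r}: rest_offset {offset} <= rest_onset {onset}")
            if prev_end is not None and onset < prev_end:
                raise ValueError(
                    f"diary {self.subject_id!r}: intervals overlap or are out of order at {onset}")
            prev_end = offset

    def total_rest(self) -> timedelta:
        return sum(((b - a) for a, b in self.intervals), timedelta(0))


@dataclass
class SubjectRecording:
    """Aligned temperature / activity / position channels for one subject.

    All three series share the 10-min grid (same start, step 600 s, same
    length).  Position is in degrees within [0, 90]; activity is
    non-negative (degrees of postural change per minute).
    """

    subject_id: str
    temperature: EquispacedSeries
    activity: EquispacedSeries
    position: EquispacedSeries
    diary: DiarySeries | None = None

    def __post_init__(self) -> None:
        for name, s in (("activity", self.activity), ("position", self.position)):
            if not self.temperature.same_grid(s):
                raise ValueError(
                    f"subject {self.subject_id!r}: {name} grid differs from temperature grid")
        if self.temperature.step != EPOCH_10MIN:
            raise ValueError(
                f"subject {self.subject_id!r}: recording grid must be 600 s, "
                f"got {self.temperature.step}")
        p = self.position.values
        if np.nanmin(p) < 0 or np.nanmax(p) > 90:
            raise ValueError(f"subject {self.subject_id!r}: position outside [0, 90] degrees")
        if np.nanmin(self.activity.values) < 0:
            raise ValueError(f"subject {self.subject_id!r}: negative activity")


# ---------------------------------------------------------------------------
# artifact filtering


@dataclass(frozen=True)
class ArtifactRule:
    """Sample-rejection rule.

    ``min_value``/``max_value`` bound the physiologically plausible range;
    ``max_step`` flags a sample whose absolute first difference from the
    previous retained sample exceeds it (None disables either check).
    """

    min_value: float | None = None
    max_value: float | None = None
    max_step: float | None = None


#: Default wrist-temperature rule: a removed sensor reads ambient
#: temperature, far below the 25-40 degC physiological band, and re-warms
#: with jumps much larger than 2 degC per 10-min epoch.
TEMPERATURE_ARTIFACT_RULE = ArtifactRule(min_value=25.0, max_value=40.0, max_step=2.0)


def filter_artifacts(series: EquispacedSeries,
                     rule: ArtifactRule = TEMPERATURE_ARTIFACT_RULE) -> EquispacedSeries:
    """Replace artifactual samples (e.g. sensor-removal episodes) with NaN.

    Length and grid are preserved.  Raises ``ValueError`` if every sample
    is flagged, which indicates a non-recoverable recording.
    """
    x = series.values.copy()
    flagged = np.zeros(x.size, dtype=bool)
    if rule.min_value is not None:
        flagged |= x < rule.min_value
    if rule.max_value is not None:
        flagged |= x > rule.max_value
    if rule.max_step is not None:
        # raw first difference between adjacent samples; flag the later one
        d = np.abs(np.diff(x))
        with np.errstate(invalid="ignore"):
            flagged[1:] |= d > rule.max_step
    n_flagged = int(flagged.sum())
    valid = ~np.isnan(x)
    if n_flagged and not (valid & ~flagged).any():
        raise ValueError(f"all samples flagged as artifacts in series {series.label!r}")
    if n_flagged:
        logger.info("filter_artifacts: flagged %d/%d samples in %r",
                    n_flagged, x.size, series.label)
    x[flagged] = np.nan
    return series.with_values(x)


# ---------------------------------------------------------------------------
# resampling to the common grid


def resample(series: EquispacedSeries, out_step: float, reducer: str) -> EquispacedSeries:
    """Aggregate onto a coarser grid anchored at ``start_time``.

    ``reducer`` is ``"mean"`` or ``"sum"``.  Output windows are half-open
    ``[t, t+out_step)``, labelled by window start.  A mean window uses the
    available samples when at least half are present, otherwise it is
    missing; a sum window is missing unless every source sample is present
    (a partial sum is not defined up to scale).  A trailing partial window
    is dropped.
    """
    if reducer not in ("mean", "sum"):
        raise ValueError(f"reducer must be 'mean' or 'sum', got {reducer!r}")
    ratio = out_step / series.step
    if abs(ratio - round(ratio)) > 1e-9 or out_step < series.step:
        raise ValueError(
            f"output step {out_step} s is not an integer multiple of input step {series.step} s")
    k = int(round(ratio))
    n_out = len(series) // k
    if n_out < 1:
        raise ValueError("series shorter than one output window")
    x = series.values[: n_out * k].reshape(n_out, k)
    present = ~np.isnan(x)
    n_present = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        if reducer == "mean":
            out = np.where(n_present >= (k + 1) // 2,
                           np.nansum(x, axis=1) / np.maximum(n_present, 1), np.nan)
        else:
            out = np.where(n_present == k, np.nansum(x, axis=1), np.nan)
    return EquispacedSeries(series.start_time, out_step, out, series.label)


def resample_to_10min(series: EquispacedSeries, reducer: str) -> EquispacedSeries:
    """Aggregate a raw logger channel into 10-min epochs (sum or mean)."""
    return resample(series, EPOCH_10MIN, reducer)


def activity_per_minute(summed: EquispacedSeries) -> EquispacedSeries:
    """Convert 10-min summed angular displacement to degrees per minute."""
    minutes = summed.step / 60.0
    return summed.with_values(summed.values / minutes, label="motor activity (deg/min)")


# ---------------------------------------------------------------------------
# per-subject percentile normalization


def normalize_percentile(series: EquispacedSeries, low_pct: float = 5.0,
                         high_pct: float = 95.0, invert: bool = False) -> EquispacedSeries:
    """Map the series onto [0, 1] via its own 5th/95th percentiles.

    ``x -> (x - p_low) / (p_high - p_low)`` clipped to [0, 1]; with
    ``invert`` the result is reflected (``1 - .``), which is how wrist
    temperature — high during rest — is brought into phase with activity
    and position.  Percentiles are computed over the whole recording,
    ignoring missing samples (linear interpolation between order
    statistics).
    """
    x = series.values
    finite = x[~np.isnan(x)]
    if np.unique(finite).size < 2:
        raise ValueError(f"cannot normalize constant series {series.label!r}")
    p_low, p_high = np.percentile(finite, [low_pct, high_pct])
    if p_high == p_low:
        raise ValueError(
            f"degenerate percentiles (p{low_pct} == p{high_pct}) in series {series.label!r}")
    out = np.clip((x - p_low) / (p_high - p_low), 0.0, 1.0)
    if invert:
        out = 1.0 - out
    suffix = " (normalized, inverted)" if invert else " (normalized)"
    return series.with_values(out, label=series.label + suffix)


# ---------------------------------------------------------------------------
# diary handling


def diary_to_binary(diary: DiarySeries, grid: EquispacedSeries) -> EquispacedSeries:
    """Binarize a rest diary on a series grid: 1 = declared rest, 0 = activity.

    An epoch scores 1 when its midpoint falls inside a rest interval, with
    closed-left / open-right membership (a midpoint exactly at rest onset
    counts as rest).
    """
    if not diary.intervals:
        logger.warning("diary_to_binary: empty diary for subject %r; all epochs scored active",
                       diary.subject_id)
        return grid.with_values(np.zeros(len(grid)), label="diary rest (binary)")
    mids = grid.timestamps() + pd.Timedelta(seconds=grid.step / 2)
    out = np.zeros(len(grid))
    for onset, offset in diary.intervals:
        out[(mids >= onset) & (mids < offset)] = 1.0
    return grid.with_values(out, label="diary rest (binary)")
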