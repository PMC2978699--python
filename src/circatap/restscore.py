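"""Diary-calibrated rest/wake scoring and its validation statistics.

A normalized series (TAP or a single channel) is thresholded into binary
rest (1) / wake (0) epochs.  Thresholds are calibrated per subject by an
exhaustive scan maximizing epoch agreement against the subject's rest
diary, then averaged over the calibration subjects.  Validation reports
the confusion matrix with rest as the positive class, a chi-square test on
contingency counts, waveform-level Pearson correlation, and the Fisher
r-to-z test for comparing two correlation coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .nonparametric import MeanWaveform
from .series import DiarySeries, EquispacedSeries, diary_to_binary

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "ScoringResult",
    "score_rest",
    "confusion_stats",
    "calibrate_threshold",
    "calibrate_thresholds",
    "chi_square_2xk",
    "waveform_correlation",
    "compare_correlations",
]


@dataclass
class ThresholdSet:
    """Per-variable rest/wake thresholds and the subjects they came from."""

    thresholds: dict[str, float]
    calibration_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, thr in self.thresholds.items():
            if not 0 <= thr <= 1:
                raise ValueError(f"threshold for {name!r} outside [0, 1]: {thr}")


@dataclass
class ScoringResult:
    """Confusion-matrix statistics with rest (1) as the positive class.

    ``agreement`` is overall accuracy (TP+TN)/total.  ``ppv``, the share of
    predicted-rest epochs that are truly rest, is reported alongside
    because verbal definitions of these rates in the actigraphy literature
    sometimes refer to predictive values.
    """

    predictions: np.ndarray
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def agreement(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def score_rest(series: EquispacedSeries, threshold: float) -> EquispacedSeries:
    """Binary rest prediction: 1 where value <= threshold, else 0.

    A value exactly at the threshold scores rest, so a recording pinned at
    0 (complete rest) is rest even under a zero threshold.  Missing epochs
    stay missing.
    """
    x = series.values
    out = np.where(np.isnan(x), np.nan, (x <= threshold).astype(float))
    return series.with_values(out, label=f"rest prediction (thr={threshold:g})")


def confusion_stats(pred: EquispacedSeries | np.ndarray,
                    truth: EquispacedSeries | np.ndarray) -> ScoringResult:
    """Epoch-level confusion counts of a prediction against diary truth.

    Missing epochs in either input are excluded from the counts.
    """
    p = pred.values if isinstance(pred, EquispacedSeries) else np.asarray(pred, float)
    t = truth.values if isinstance(truth, EquispacedSeries) else np.asarray(truth, float)
    if p.shape != t.shape:
        raise ValueError("prediction and truth differ in length")
    ok = ~np.isnan(p) & ~np.isnan(t)
    if not ok.any():
        raise ValueError("no overlapping scored epochs")
    p, t = p[ok], t[ok]
    return ScoringResult(
        predictions=p,
        tp=int(((p == 1) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def _truth_on_grid(truth, grid: EquispacedSeries) -> EquispacedSeries:
    if isinstance(truth, DiarySeries):
        return diary_to_binary(truth, grid)
    return truth


def calibrate_threshold(series_by_subject: dict[str, EquispacedSeries],
                        truth_by_subject: dict[str, EquispacedSeries | DiarySeries],
                        grid_step: float = 0.01) -> tuple[float, dict[str, float]]:
    """Calibrate one variable's rest/wake threshold against diaries.

    For each calibration subject the threshold grid [0, 1] is scanned
    exhaustively at ``grid_step`` and the agreement-maximizing value kept
    (ties broken toward the lower threshold); the final threshold is the
    mean over subjects.  Returns ``(final, per_subject)``.  Subjects
    without truth are excluded with a warning.
    """
    per_subject: dict[str, float] = {}
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    for sid, series in series_by_subject.items():
        truth = truth_by_subject.get(sid)
        if truth is None:
            logger.warning("calibrate_threshold: subject %r has no diary; excluded", sid)
            continue
        t = _truth_on_grid(truth, series)
        x, tv = series.values, t.values
        ok = ~np.isnan(x) & ~np.isnan(tv)
        x, tv = x[ok], tv[ok]
        # agreement(thr) = mean((x <= thr) == truth); vectorized over the grid
        agree = ((x[None, :] <= grid[:, None]) == (tv[None, :] == 1)).mean(axis=1)
        per_subject[sid] = float(grid[int(np.argmax(agree))])  # argmax takes first = lowest
    if not per_subject:
        raise ValueError("no calibration subjects with diaries")
    return float(np.mean(list(per_subject.values()))), per_subject


def calibrate_thresholds(series_by_variable: dict[str, dict[str, EquispacedSeries]],
                         truth_by_subject: dict[str, EquispacedSeries | DiarySeries],
                         calibration_subjects: list[str] | None = None,
                         grid_step: float = 0.01) -> ThresholdSet:
    """Calibrate every variable (e.g. T, A, P, TAP) on the same subjects."""
    thresholds = {}
    subjects_used: list[str] = []
    for name, by_subject in series_by_variable.items():
        if calibration_subjects is not None:
            by_subject = {s: v for s, v in by_subject.items() if s in calibration_subjects}
        thr, per_subject = calibrate_threshold(by_subject, truth_by_subject, grid_step)
        thresholds[name] = thr
        subjects_used = sorted(per_subject)
    return ThresholdSet(thresholds=thresholds, calibration_subjects=subjects_used)


def chi_square_2xk(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table of non-negative counts.

    Returns ``(statistic, p_value)`` with (rows-1)(cols-1) degrees of
    freedom and no continuity correction.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def waveform_correlation(var_waveform: MeanWaveform,
                         rest_waveform: MeanWaveform) -> tuple[float, float]:
    """Pearson correlation across time-of-day bins between a variable's
    mean waveform and the rest-probability waveform, with its two-sided p.
    """
    if len(var_waveform.values) != len(rest_waveform.values):
        raise ValueError("waveforms are not on the same bin grid")
    x, y = var_waveform.values, rest_waveform.values
    ok = ~np.isnan(x) & ~np.isnan(y)
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise ValueError("constant waveform: correlation undefined")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p-value of the Fisher r-to-z test for two independent
    correlation coefficients:

        z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError(f"sample size must exceed 3, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(2 * stats.norm.sf(abs(z)))
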