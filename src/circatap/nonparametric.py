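"""Non-parametric circadian rhythm statistics and the Circadian Function
Index (CFI).

Implements the classical rest-activity statistics: interdaily stability
(IS), intradaily variability (IV), the mean 24-h waveform, the L5/M10
window scan (lowest 5 h / highest 10 h), relative amplitude (RA), and the
CFI that averages IS, the inverted-normalized IV, and RA into a single
circadian-robustness score on [0, 1].

With ``p`` time-of-day bins per day and ``n`` retained bins overall,

    IS = n * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2)

where ``xbar_h`` is the across-days mean of bin ``h``: the share of the
total variance explained by the average 24-h profile.  IS is 1 when the
pattern repeats exactly every day and has expectation ~1/(number of days)
for white noise.

    IV = n * sum_i (x_i - x_{i-1})^2 / ((n - 1) * sum_i (x_i - xbar)^2)

the normalized mean-square successive difference: ~0 for a smooth
sinusoid (closed form 2*(1 - cos(2*pi/p)) per cycle of p samples) and ~2
for white noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import EquispacedSeries

__all__ = [
    "MeanWaveform",
    "NonparametricSummary",
    "bin_series",
    "interdaily_stability",
    "intradaily_variability",
    "mean_waveform",
    "group_waveform",
    "l5_m10",
    "relative_amplitude",
    "circadian_function_index",
    "summarize",
    "write_summary_tsv",
]

DAY_S = 86400.0

L5_HOURS = 5.0
M10_HOURS = 10.0


@dataclass
class MeanWaveform:
    """Average 24-h profile: one mean (and SEM) per time-of-day bin."""

    bin_step: float
    values: np.ndarray
    sem: np.ndarray
    n_days: int
    start_second: float = 0.0  # clock seconds-of-day of bin 0

    def __post_init__(self) -> None:
        n = len(self.values)
        if abs(n * self.bin_step - DAY_S) > 1e-6:
            raise ValueError(f"{n} bins of {self.bin_step} s do not cover 24 h")

    def bin_clock_seconds(self) -> np.ndarray:
        """Clock time (seconds of day) of each bin start."""
        return (self.start_second + np.arange(len(self.values)) * self.bin_step) % DAY_S


@dataclass
class NonparametricSummary:
    IS: float
    IV: float
    RA: float
    L5_mid: float   # seconds of day
    M10_mid: float  # seconds of day
    VL5: float
    VM10: float
    CFI: float


def bin_series(series: EquispacedSeries, bin_step: float) -> EquispacedSeries:
    """Mean-bin a series onto a coarser grid (no-op if already there)."""
    if bin_step == series.step:
        return series
    from .series import resample
    return resample(series, bin_step, "mean")


def _day_matrix(series: EquispacedSeries, bin_step: float,
                max_missing_frac: float = 0.3) -> np.ndarray:
    """Whole-day (d, p) matrix of binned values.

    Days with more than ``max_missing_frac`` missing bins are dropped
    entirely so a ragged day cannot distort the across-days bin means.
    """
    binned = bin_series(series, bin_step)
    p = int(round(DAY_S / bin_step))
    if abs(p * bin_step - DAY_S) > 1e-6:
        raise ValueError(f"bin_step {bin_step} s does not divide 24 h")
    d = len(binned) // p
    if d < 1:
        raise ValueError("series covers less than one complete day")
    mat = binned.values[: d * p].reshape(d, p)
    keep = np.isnan(mat).mean(axis=1) <= max_missing_frac
    if not keep.any():
        raise ValueError("every day exceeds the missing-data limit")
    return mat[keep]


def interdaily_stability(series: EquispacedSeries, bin_step: float = 3600.0) -> float:
    """Day-to-day constancy of the 24-h pattern, in [0, 1] up to sampling error.

    Requires at least two complete days.
    """
    mat = _day_matrix(series, bin_step)
    if mat.shape[0] < 2:
        raise ValueError("interdaily stability requires >= 2 complete days")
    x = mat.ravel()
    valid = ~np.isnan(x)
    n = int(valid.sum())
    xbar = x[valid].mean()
    denom = ((x[valid] - xbar) ** 2).sum()
    if denom == 0:
        raise ValueError("constant series: interdaily stability undefined")
    hour_means = np.nanmean(mat, axis=0)
    p = mat.shape[1]
    num = n * np.nansum((hour_means - xbar) ** 2)
    return float(num / (p * denom))


def intradaily_variability(series: EquispacedSeries, bin_step: float | None = 3600.0) -> float:
    """Fragmentation of the rhythm: ~0 for a sinusoid, ~2 for white noise.

    ``bin_step=None`` computes IV on the native sampling grid.
    """
    binned = series if bin_step is None else bin_series(series, bin_step)
    x = binned.values
    valid = ~np.isnan(x)
    n = int(valid.sum())
    if n < 2:
        raise ValueError("intradaily variability requires >= 2 bins")
    xbar = x[valid].mean()
    denom = ((x[valid] - xbar) ** 2).sum()
    if denom == 0:
        raise ValueError("constant series: intradaily variability undefined")
    both = valid[1:] & valid[:-1]
    diffs = (x[1:] - x[:-1])[both]
    return float(n * (diffs ** 2).sum() / ((n - 1) * denom))


def mean_waveform(series: EquispacedSeries, bin_step: float | None = None) -> MeanWaveform:
    """Average 24-h profile of one subject: per-bin mean and SEM across days.

    Defaults to the series' native resolution.  Requires at least one
    complete day; the waveform starts at the clock time of the first
    sample.
    """
    if bin_step is None:
        bin_step = series.step
    binned = bin_series(series, bin_step)
    p = int(round(DAY_S / bin_step))
    if abs(p * bin_step - DAY_S) > 1e-6:
        raise ValueError(f"bin_step {bin_step} s does not divide 24 h")
    d = len(binned) // p
    if d < 1:
        raise ValueError("series covers less than one complete day")
    mat = binned.values[: d * p].reshape(d, p)
    n_per_bin = (~np.isnan(mat)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1) if d > 1 else np.zeros(p)
        sem = np.where(n_per_bin > 1, sd / np.sqrt(np.maximum(n_per_bin, 1)), 0.0)
    start = series.start_time
    start_second = start.hour * 3600 + start.minute * 60 + start.second
    return MeanWaveform(bin_step, means, sem, n_days=d, start_second=float(start_second))


def group_waveform(waveforms: list[MeanWaveform]) -> MeanWaveform:
    """Group-level profile: per-bin mean and SEM across subjects' waveforms."""
    if not waveforms:
        raise ValueError("no waveforms given")
    ref = waveforms[0]
    for w in waveforms[1:]:
        if w.bin_step != ref.bin_step or w.start_second != ref.start_second:
            raise ValueError("waveforms are not on the same time-of-day grid")
    mat = np.vstack([w.values for w in waveforms])
    k = mat.shape[0]
    means = np.nanmean(mat, axis=0)
    sem = (np.nanstd(mat, axis=0, ddof=1) / np.sqrt(k)) if k > 1 else np.zeros(mat.shape[1])
    return MeanWaveform(ref.bin_step, means, sem, n_days=k, start_second=ref.start_second)


def _contiguous_circular_run(candidates: np.ndarray, n: int) -> np.ndarray | None:
    """The candidates ordered as one contiguous run modulo n, else None."""
    if candidates.size == n:
        return candidates
    present = np.zeros(n, dtype=bool)
    present[candidates] = True
    # a single circular run has exactly one 0->1 transition
    starts = np.flatnonzero(present & ~np.roll(present, 1))
    if starts.size != 1:
        return None
    return (starts[0] + np.arange(candidates.size)) % n


def _circular_window_means(values: np.ndarray, width: int) -> np.ndarray:
    ext = np.concatenate([values, values[: width - 1]])
    kernel = np.ones(width) / width
    return np.convolve(ext, kernel, mode="valid")


def l5_m10(waveform: MeanWaveform) -> tuple[float, float, float, float]:
    """Scan circular 5-h and 10-h windows of the 24-h profile.

    Returns ``(L5_mid, VL5, M10_mid, VM10)``: the midpoint clock times
    (seconds of day) and mean values of the five consecutive hours with
    the lowest values and the ten consecutive hours with the highest.
    Windows wrap across midnight.  When several windows tie — e.g. a 5-h
    window sliding inside a longer flat trough — the window centred in the
    tied run is returned, so L5 of a flat 8-h rest phase sits at the
    phase midpoint; a non-contiguous tie falls back to the earliest clock
    time.
    """
    v = waveform.values
    if np.isnan(v).any():
        raise ValueError("waveform contains missing bins; cannot scan windows")
    clock = waveform.bin_clock_seconds()
    n = len(v)

    def scan(width_s: float, highest: bool) -> tuple[float, float]:
        width = int(round(width_s / waveform.bin_step))
        if width > n:
            raise ValueError("window longer than one day")
        means = _circular_window_means(v, width)
        best = float(means.max()) if highest else float(means.min())
        candidates = np.flatnonzero(np.isclose(means, best, rtol=0, atol=1e-12))
        if candidates.size > 1:
            run = _contiguous_circular_run(candidates, n)
            if run is not None:
                start = run[len(run) // 2]
            else:
                start = candidates[np.argmin(clock[candidates])]
        else:
            start = candidates[0]
        mid = (clock[start] + width_s / 2.0) % DAY_S
        return mid, float(means[start])

    l5_mid, vl5 = scan(L5_HOURS * 3600, highest=False)
    m10_mid, vm10 = scan(M10_HOURS * 3600, highest=True)
    return l5_mid, vl5, m10_mid, vm10


def relative_amplitude(vl5: float, vm10: float) -> float:
    """RA = (VM10 - VL5) / (VM10 + VL5); 0 for a flat profile."""
    if vl5 < 0 or vm10 < 0:
        raise ValueError("relative amplitude requires non-negative window means")
    if vm10 + vl5 == 0:
        return 0.0
    return (vm10 - vl5) / (vm10 + vl5)


def circadian_function_index(is_: float, iv: float, ra: float) -> float:
    """CFI = (IS + clip(1 - IV/2, 0, 1) + RA) / 3.

    IV is inverted and normalized so that 0 maps to noise and 1 to a
    smooth sinusoid; the clip guards against IV > 2, which occurs on real
    data.  0 = absence of circadian rhythmicity, 1 = robust rhythm.
    """
    if not 0 <= is_ <= 1 + 1e-9:
        raise ValueError(f"IS out of range [0, 1]: {is_}")
    if not 0 <= ra <= 1 + 1e-9:
        raise ValueError(f"RA out of range [0, 1]: {ra}")
    if iv < 0:
        raise ValueError(f"IV must be non-negative: {iv}")
    iv_inv = min(max(1.0 - iv / 2.0, 0.0), 1.0)
    return (min(is_, 1.0) + iv_inv + min(ra, 1.0)) / 3.0


def summarize(series: EquispacedSeries, is_iv_bin_step: float = 3600.0,
              waveform_bin_step: float | None = None) -> NonparametricSummary:
    """Full non-parametric characterization of one series.

    IS/IV default to hourly binning; the L5/M10 scan runs on the mean
    waveform at the series' native resolution.
    """
    is_ = interdaily_stability(series, is_iv_bin_step)
    iv = intradaily_variability(series, is_iv_bin_step)
    wf = mean_waveform(series, waveform_bin_step)
    l5_mid, vl5, m10_mid, vm10 = l5_m10(wf)
    ra = relative_amplitude(vl5, vm10)
    cfi = circadian_function_index(min(is_, 1.0), iv, ra)
    return NonparametricSummary(IS=is_, IV=iv, RA=ra, L5_mid=l5_mid, M10_mid=m10_mid,
                                VL5=vl5, VM10=vm10, CFI=cfi)


def _hhmm(seconds: float) -> str:
    m = int(round(seconds / 60.0)) % (24 * 60)
    return f"{m // 60:02d}:{m % 60:02d}"


def write_summary_tsv(summaries: dict[str, NonparametricSummary], path) -> None:
    """Tabulate summaries, one row per variable, clock times as hh:mm."""
    with open(path, "w") as fh:
        fh.write("variable\tIS\tIV\tRA\tL5\tM10\tVL5\tVM10\tCFI\n")
        for name, s in summaries.items():
            fh.write(f"{name}\t{s.IS:.4f}\t{s.IV:.4f}\t{s.RA:.4f}\t"
                     f"{_hhmm(s.L5_mid)}\t{_hhmm(s.M10_mid)}\t"
                     f"{s.VL5:.4f}\t{s.VM10:.4f}\t{s.CFI:.4f}\n")
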