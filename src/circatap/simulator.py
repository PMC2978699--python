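"""Synthetic circadian recordings: square/sinusoidal daily patterns mixed
with 1/f fractal noise and rest-activity instability, plus full synthetic
subject recordings (temperature, activity, position, diary) for validating
the TAP pipeline end to end.

The generator emulates week-long free-living recordings of healthy young
adults: a nocturnal rest phase of ~8 h (the activity phase occupies 66% of
each 24-h day), diurnal activity, optional early-afternoon naps, and
per-subject pink noise.  The noise percentage is a convex mixing weight:
0% leaves the daily pattern untouched, 100% replaces it entirely with
amplitude-matched noise — a continuous gradient from a robust rhythm to an
arrhythmic signal.  Instability jitters each day's activity-phase onset
and offset, degrading day-to-day stability without changing the mean
rest/activity ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .series import DiarySeries, EquispacedSeries, SubjectRecording

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SubjectProfile",
    "SyntheticSubject",
    "base_wave",
    "fractal_noise",
    "mix_noise",
    "apply_instability",
    "simulate_tap",
    "synth_subject",
    "synth_cohort",
    "write_cohort",
    "truth_to_diary",
    "synthesize_accel",
]

DAY_S = 86400.0
_DEFAULT_START = datetime(2024, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated series or subject.

    ``noise_pct`` and ``instability_pct`` are percentages in [0, 100];
    ``activity_fraction`` is the share of each 24-h day spent in the
    activity phase (default 0.66, i.e. ~8.2 h of nocturnal rest).
    Identical config + seed yields bit-identical output.
    """

    waveform: str = "square"
    activity_fraction: float = 0.66
    noise_pct: float = 0.0
    instability_pct: float = 0.0
    days: int = 7
    step: float = 600.0
    seed: int = 0
    noise_kind: str = "fractal"

    def __post_init__(self) -> None:
        if self.waveform not in ("square", "sine"):
            raise ValueError(f"waveform must be 'square' or 'sine', got {self.waveform!r}")
        if not 0 < self.activity_fraction < 1:
            raise ValueError("activity_fraction must lie in (0, 1)")
        for name in ("noise_pct", "instability_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.noise_kind not in ("fractal", "gaussian"):
            raise ValueError(f"noise_kind must be 'fractal' or 'gaussian', got {self.noise_kind!r}")

    @property
    def epochs_per_day(self) -> int:
        epd = DAY_S / self.step
        if abs(epd - round(epd)) > 1e-9:
            raise ValueError(f"step {self.step} s does not divide 24 h")
        return int(round(epd))

    @property
    def n_rest_epochs(self) -> int:
        epd = self.epochs_per_day
        return epd - int(round(self.activity_fraction * epd))


@dataclass(frozen=True)
class SubjectProfile:
    """Physical channel levels of a synthetic subject.

    Wrist temperature runs high (``t_rest``) during rest and low
    (``t_wake``) during arousal; activity peaks at ``a_wake`` deg/min and
    position moves between near-horizontal ``p_rest`` and near-vertical
    ``p_wake``.  ``nap_probability`` is the per-day chance of an
    early-afternoon nap of 30-60 min, recorded in both truth and diary.
    """

    t_rest: float = 35.0
    t_wake: float = 31.0
    a_wake: float = 60.0
    p_rest: float = 5.0
    p_wake: float = 70.0
    nap_probability: float = 0.25
    #: moving-average width (10-min epochs) applied to the temperature
    #: pattern: skin temperature changes by vasodilation over tens of
    #: minutes, never stepwise. 1 disables smoothing.
    t_smooth_epochs: int = 3


@dataclass
class SyntheticSubject:
    recording: SubjectRecording
    truth: EquispacedSeries  # 1 = generative rest epoch
    config: SimulationConfig
    profile: SubjectProfile = field(default_factory=SubjectProfile)


# ---------------------------------------------------------------------------
# primitive signal generators


def base_wave(config: SimulationConfig,
              start_time: datetime = _DEFAULT_START) -> EquispacedSeries:
    """Noise-free daily pattern on [0, 1], repeated for ``days`` days.

    Square: 1 during the activity phase, 0 during the rest phase; the rest
    phase starts at midnight, so with the default configuration each day
    has round(0.66*144) = 95 active and 49 resting 10-min epochs.  Sine:
    0.5 - 0.5*cos phased so the minimum falls at the rest-phase midpoint.
    """
    epd = config.epochs_per_day
    n_rest = config.n_rest_epochs
    if config.waveform == "square":
        day = np.ones(epd)
        day[:n_rest] = 0.0
    else:
        t = np.arange(epd) * config.step
        rest_mid = n_rest * config.step / 2.0
        day = 0.5 - 0.5 * np.cos(2 * np.pi * (t - rest_mid) / DAY_S)
    values = np.tile(day, config.days)
    return EquispacedSeries(start_time, config.step, values,
                            label=f"{config.waveform} base wave")


def fractal_noise(n: int, seed: int | np.random.Generator,
                  step: float = 600.0, start_time: datetime = _DEFAULT_START,
                  exponent: float = 1.0) -> EquispacedSeries:
    """Pink (1/f) noise by spectral synthesis, standardized to zero mean
    and unit variance.

    Fourier amplitudes are drawn proportional to f^(-exponent/2) — power
    spectral density proportional to 1/f^exponent — with uniform random
    phases, then inverse-transformed.  ``exponent=1`` is the canonical
    fractal noise of biological signals.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    x = (x - x.mean()) / x.std()
    return EquispacedSeries(start_time, step, x, label="fractal noise")


def _gaussian_noise(n: int, rng: np.random.Generator, step: float,
                    start_time: datetime) -> EquispacedSeries:
    return EquispacedSeries(start_time, step, rng.standard_normal(n), label="gaussian noise")


def mix_noise(base: EquispacedSeries, noise: EquispacedSeries,
              noise_pct: float) -> EquispacedSeries:
    """Convex mixture ``(1-a)*base + a*noise'`` with ``a = noise_pct/100``.

    The unit-variance noise is first re-centred at the base wave's
    mid-range and scaled to half its peak-to-trough range, so 100% noise
    has the amplitude of the pattern it replaces; the mixture is clipped
    to [0, 1].
    """
    if len(base) != len(noise):
        raise ValueError("base and noise differ in length")
    alpha = noise_pct / 100.0
    if not 0 <= alpha <= 1:
        raise ValueError(f"noise_pct must lie in [0, 100], got {noise_pct}")
    lo, hi = float(np.nanmin(base.values)), float(np.nanmax(base.values))
    scaled = (lo + hi) / 2.0 + noise.values * (hi - lo) / 2.0
    out = np.clip((1 - alpha) * base.values + alpha * scaled, 0.0, 1.0)
    return base.with_values(out, label=f"{base.label} + {noise_pct:g}% noise")


def apply_instability(config: SimulationConfig, instability_pct: float | None = None,
                      seed: int | np.random.Generator | None = None,
                      start_time: datetime = _DEFAULT_START) -> EquispacedSeries:
    """Square wave whose daily activity onset/offset are jittered.

    Each day's activity-phase onset and offset are shifted independently
    by uniform offsets within +/-(instability_pct/100) * 24 h / 2 — a 20%
    instability allows boundary displacements of up to 2.4 h — clamped so
    a phase can never invert.  The mean activity/rest ratio is preserved
    in expectation.  Defined for the square waveform only.
    """
    if config.waveform != "square":
        raise ValueError("instability is defined on square-wave phase boundaries only")
    pct = config.instability_pct if instability_pct is None else instability_pct
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    epd = config.epochs_per_day
    n_rest = config.n_rest_epochs
    half_window = (pct / 100.0) * DAY_S / 2.0
    active = np.zeros(config.days * epd, dtype=float)
    mids = (np.arange(config.days * epd) + 0.5) * config.step
    for day in range(config.days):
        onset = day * DAY_S + n_rest * config.step
        offset = (day + 1) * DAY_S
        onset += rng.uniform(-half_window, half_window)
        offset += rng.uniform(-half_window, half_window)
        if onset >= offset - config.step:
            logger.warning("apply_instability: phase inversion on day %d clamped", day)
            onset = offset - config.step
        active[(mids >= onset) & (mids < offset)] = 1.0
    return EquispacedSeries(start_time, config.step, active,
                            label=f"square wave, {pct:g}% instability")


def simulate_tap(config: SimulationConfig,
                 start_time: datetime = _DEFAULT_START) -> EquispacedSeries:
    """Full simulated TAP-like series: daily pattern (+instability) + noise."""
    # separate streams so the noise realization is identical across
    # instability settings at the same seed (and vice versa)
    sched_ss, noise_ss = np.random.SeedSequence(config.seed).spawn(2)
    if config.waveform == "square" and config.instability_pct > 0:
        wave = apply_instability(config, seed=np.random.default_rng(sched_ss),
                                 start_time=start_time)
    else:
        if config.instability_pct > 0:
            raise ValueError("instability is defined for the square waveform only")
        wave = base_wave(config, start_time)
    if config.noise_pct == 0:
        return wave
    n = len(wave)
    noise_rng = np.random.default_rng(noise_ss)
    if config.noise_kind == "fractal":
        noise = fractal_noise(n, noise_rng, step=config.step, start_time=start_time)
    else:
        noise = _gaussian_noise(n, noise_rng, config.step, start_time)
    return mix_noise(wave, noise, config.noise_pct)


# ---------------------------------------------------------------------------
# whole-subject synthesis


def _truth_pattern(config: SimulationConfig, profile: SubjectProfile,
                   rng: np.random.Generator, start_time: datetime) -> np.ndarray:
    """Binary activity schedule (1 = active) with instability and naps."""
    if config.instability_pct > 0:
        active = apply_instability(config, seed=rng, start_time=start_time).values.copy()
    else:
        epd = config.epochs_per_day
        day = np.ones(epd)
        day[: config.n_rest_epochs] = 0.0
        active = np.tile(day, config.days)
    if profile.nap_probability > 0:
        epd = config.epochs_per_day
        for day in range(config.days):
            if rng.uniform() < profile.nap_probability:
                # early-afternoon nap: onset 15:00-16:30, duration 30-60 min
                onset_s = rng.uniform(15.0, 16.5) * 3600
                dur = rng.integers(3, 7)  # epochs of 600 s
                i0 = day * epd + int(onset_s // config.step)
                active[i0: i0 + int(dur)] = 0.0
    return active


def truth_to_diary(truth: EquispacedSeries, subject_id: str = "") -> DiarySeries:
    """Rest intervals from contiguous runs of truth == 1 (rest)."""
    rest = truth.values == 1
    ts = truth.timestamps()
    step = timedelta(seconds=truth.step)
    intervals: list[tuple[datetime, datetime]] = []
    i = 0
    n = len(rest)
    while i < n:
        if rest[i]:
            j = i
            while j + 1 < n and rest[j + 1]:
                j += 1
            intervals.append((ts[i].to_pydatetime(), (ts[j] + step).to_pydatetime()))
            i = j + 1
        else:
            i += 1
    return DiarySeries(intervals, subject_id=subject_id)


def _noisy_channel(pattern: np.ndarray, config: SimulationConfig,
                   rng: np.random.Generator, start_time: datetime) -> np.ndarray:
    """Mix a channel-specific noise realization into the arousal pattern."""
    series = EquispacedSeries(start_time, config.step, pattern, "arousal pattern")
    if config.noise_pct == 0:
        return pattern.astype(float)
    if config.noise_kind == "fractal":
        noise = fractal_noise(len(pattern), rng, step=config.step, start_time=start_time)
    else:
        noise = _gaussian_noise(len(pattern), rng, config.step, start_time)
    return mix_noise(series, noise, config.noise_pct).values


def synth_subject(config: SimulationConfig, profile: SubjectProfile = SubjectProfile(),
                  subject_id: str = "s00",
                  start_time: datetime = _DEFAULT_START) -> SyntheticSubject:
    """One synthetic subject: aligned T/A/P 10-min channels, diary, truth.

    The generative schedule is a square activity pattern (with the
    configured instability and optional naps).  Temperature follows the
    inverted pattern — high (``t_rest``) during rest, low (``t_wake``)
    during activity — and activity/position follow it directly, each
    channel degraded by an independent noise realization at the configured
    noise percentage.  The diary restates the generative truth.
    """
    schedule_rng, t_rng, a_rng, p_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)]
    active = _truth_pattern(config, profile, schedule_rng, start_time)
    truth = EquispacedSeries(start_time, config.step, 1.0 - active, label="truth rest (binary)")

    t_pattern = active.astype(float)
    if profile.t_smooth_epochs > 1:
        kernel = np.ones(profile.t_smooth_epochs) / profile.t_smooth_epochs
        t_pattern = np.convolve(t_pattern, kernel, mode="same")
    arousal_t = _noisy_channel(t_pattern, config, t_rng, start_time)
    arousal_a = _noisy_channel(active, config, a_rng, start_time)
    arousal_p = _noisy_channel(active, config, p_rng, start_time)

    temp = profile.t_rest - (profile.t_rest - profile.t_wake) * arousal_t
    act = profile.a_wake * arousal_a
    pos = profile.p_rest + (profile.p_wake - profile.p_rest) * arousal_p

    recording = SubjectRecording(
        subject_id=subject_id,
        temperature=EquispacedSeries(start_time, config.step, temp,
                                     "wrist temperature (degC)"),
        activity=EquispacedSeries(start_time, config.step, act, "motor activity (deg/min)"),
        position=EquispacedSeries(start_time, config.step, pos, "body position (deg)"),
        diary=truth_to_diary(truth, subject_id),
    )
    return SyntheticSubject(recording=recording, truth=truth, config=config, profile=profile)


def synth_cohort(n_subjects: int, config: SimulationConfig,
                 profile: SubjectProfile = SubjectProfile(),
                 start_time: datetime = _DEFAULT_START) -> list[SyntheticSubject]:
    """Independent subjects with per-subject seeds derived from the config seed."""
    children = np.random.SeedSequence(config.seed).spawn(n_subjects)
    out = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        sub_config = replace(config, seed=sub_seed)
        out.append(synth_subject(sub_config, profile, subject_id=f"s{i:02d}",
                                 start_time=start_time))
    return out


def write_cohort(subjects: list[SyntheticSubject], outdir: str | Path) -> None:
    """Serialize a cohort: per-subject channel CSVs, one diary.csv, truth.csv."""
    from .io import write_diary_csv, write_series_csv, write_temperature_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diaries = {}
    with open(outdir / "truth.csv", "w") as truth_fh:
        truth_fh.write("subject_id,timestamp,rest\n")
        for sub in subjects:
            sid = sub.recording.subject_id
            write_temperature_csv(sub.recording.temperature, outdir / f"{sid}_temperature.csv")
            write_series_csv(sub.recording.activity, outdir / f"{sid}_activity.csv")
            write_series_csv(sub.recording.position, outdir / f"{sid}_position.csv")
            diaries[sid] = sub.recording.diary
            for ts, v in zip(sub.truth.timestamps(), sub.truth.values):
                truth_fh.write(f"{sid},{ts.isoformat()},{int(v)}\n")
    write_diary_csv(diaries, outdir / "diary.csv")


# ---------------------------------------------------------------------------
# raw accelerometer synthesis (for exercising the derivation pipeline)


def synthesize_accel(position_deg: np.ndarray,
                     step_activity_deg: np.ndarray) -> np.ndarray:
    """Unit orientation vectors whose tilt and inter-sample angles match
    the given 30-s position (degrees in [0, 90]) and angular-displacement
    (degrees per step; first entry ignored) sequences.

    The x-component is fixed by the tilt; the azimuth about the x-axis is
    advanced so consecutive vectors subtend the requested angle, clamped
    to the geometrically feasible range.  Useful for round-trip tests of
    the activity/position derivation.
    """
    p = np.radians(np.asarray(position_deg, dtype=float))
    a = np.radians(np.asarray(step_activity_deg, dtype=float))
    if p.shape != a.shape:
        raise ValueError("position and activity sequences differ in length")
    n = p.size
    out = np.empty((n, 3))
    phi = 0.0
    out[0] = (math.sin(p[0]), math.cos(p[0]) * math.cos(phi), math.cos(p[0]) * math.sin(phi))
    for i in range(1, n):
        c1, c2 = math.cos(p[i - 1]), math.cos(p[i])
        s1, s2 = math.sin(p[i - 1]), math.sin(p[i])
        if c1 * c2 == 0:
            dphi = 0.0
        else:
            cos_dphi = (math.cos(a[i]) - s1 * s2) / (c1 * c2)
            dphi = math.acos(min(1.0, max(-1.0, cos_dphi)))
        phi += dphi
        out[i] = (s2, c2 * math.cos(phi), c2 * math.sin(phi))
    return out
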