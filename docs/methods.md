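# Methods

## Signal model and processing chain

The package assumes three co-recorded channels per subject: wrist skin
temperature sampled every 10 min, and a 3-axis arm accelerometer sampled
every 30 s from which motor activity and body position are derived. Skin
temperature at the wrist rises during rest (parasympathetically driven
vasodilation) and falls with arousal; activity and position behave the
opposite way, which is why the normalized temperature is inverted before
fusion.

**Actigraphy derivation.** Each 30-s accelerometer reading is treated as a
static tilt measurement — gravity is assumed to dominate linear
acceleration at this sampling interval, so no gravity separation is
attempted. Motor activity is the angle (arccos of the normalized dot
product, degrees) between consecutive orientation vectors; summed over a
10-min epoch it is the total angular path, divided by 10 to give deg/min.
Body position is `arcsin(|x|/‖v‖)`: the unsigned elevation of the device
X-axis (worn parallel to the humerus) over the horizontal plane, so lying
reads 0° and upright 90°, and arm-up vs arm-down are not distinguished. A
zero-magnitude reading carries no orientation and becomes missing. The
first sample of a recording has no predecessor; its displacement is set to
0 rather than missing so the first epoch stays defined.

**Artifact filtering.** Removing the temperature sensor exposes it to
ambient air; the default rule flags samples outside 25–40 °C and samples
whose absolute first difference exceeds 2 °C per 10-min step (vasomotor
changes are slower than that). The jump test uses raw adjacent
differences and flags the later sample of an offending pair; comparing
against the last *retained* sample instead would cascade after any
genuine level shift and erase whole phases. Flagging everything is an
error, not an empty series. Accelerometer channels are only flagged on
explicit logger error codes (zero vectors).

**Gridding and missingness.** Raw 30-s channels are aggregated onto the
half-open 10-min windows `[t, t+600 s)` anchored at the first common
timestamp: activity summed (a window missing any sample is missing, since
a partial sum is biased), position averaged (defined when ≥ 50% of
samples are present). Missing values are NaN throughout; they are never
dropped, so day-reshaping arithmetic stays valid.

**Normalization and fusion.** Each channel is mapped through its own
5th/95th percentiles (linear interpolation, missing ignored), clipped to
[0, 1] — keeping TAP itself in [0, 1] so thresholds and CFI bounds hold —
and temperature inverted. TAP is the equal-weight epoch mean; an epoch
missing any component is missing by default (averaging 2 of 3 channels
silently changes the variable's meaning), with an opt-in
mean-of-available policy. Weights are configurable for sensitivity
studies only.

**Diaries.** Rest intervals binarize onto the series grid by epoch
midpoint with closed-left/open-right membership — an unambiguous,
testable boundary rule.

## Non-parametric statistics

IS and IV use the standard defining sums (see README). Defaults: hourly
bins for IS/IV — the bin width is exposed because published values shift
in the third decimal depending on this choice — and the native 10-min
resolution for the mean waveform and the circular L5/M10 window scans.
Days with more than 30% missing bins are excluded from the day matrix;
remaining sums adjust `n` to the retained bin count (with unequal
per-bin day counts IS may slightly exceed 1; it is clipped only inside
the CFI).

L5/M10 scan every circular window position at waveform resolution. Ties —
generic for square-like profiles, where many windows fit inside a flat
trough — resolve to the window centred in the contiguous tied run, so L5
of a flat 8-h rest phase is the phase midpoint; non-contiguous ties fall
back to the earliest clock time. Midpoints are reported as clock seconds
of day.

CFI averages IS, the inverted-normalized IV `clip(1 − IV/2, 0, 1)` — the
clip because IV exceeds 2 on fragmented real data — and RA. It is
monotone increasing in IS and RA and decreasing in IV by construction.

## Rest/wake scoring

A value at or below the threshold scores rest: equality maps a series
pinned at 0 ("complete rest") to rest, which the strict-inequality
reading would leave undefined. Calibration scans thresholds over [0, 1]
at step 0.01 per subject, maximizes diary agreement, breaks ties toward
the lower threshold, and averages across calibration subjects.
Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and agreement
(TP+TN)/total use rest as the positive class; PPV TP/(TP+FP) is reported
alongside because some verbal definitions of "sensitivity" in the
actigraphy literature actually describe predictive values. The χ² test is
Pearson's without continuity correction; the two-correlation comparison
is the Fisher r-to-z form with the number of waveform bins as the
default n.

## Simulator

The generator's defaults encode the target study conditions: 7-day
recordings on the 10-min grid, activity phase 66% of each 24-h day
(≈ 8.2 h nocturnal rest, placed at 00:00–08:10), square or sinusoidal
shape (the sine's minimum at the rest-phase midpoint).

*Fractal noise* is pink (1/f) noise by spectral synthesis — amplitudes ∝
f^(−1/2), uniform random phases, inverse FFT, standardized to zero mean
and unit variance; the spectral exponent is configurable. *Noise X%* is a
convex mixture: the noise is re-centred at the wave's mid-range, scaled
to half its peak-to-trough range, mixed with weight X/100 and clipped to
[0, 1], giving a continuous gradient from a clean rhythm (0%) to a signal
independent of the pattern (100%). *Instability X%* jitters each day's
activity onset and offset independently by uniform offsets within
±(X/100)·24 h/2 (so 20% allows ±2.4 h per boundary), clamped against
phase inversion; the mean activity/rest ratio is preserved in
expectation. The schedule jitter and the noise use separate seeded
streams so that comparisons across instability settings at a fixed seed
hold the noise realization fixed.

Synthetic subjects map the (jittered) binary schedule, plus optional
early-afternoon naps (per-day probability 0.25, 30–60 min, 15:00–16:30
onset), onto physical channels: temperature between 31 °C (wake) and
35 °C (rest) after a 30-min moving-average smoothing of the schedule —
vasomotor dynamics change skin temperature over tens of minutes, and an
instantaneous 4 °C step would itself look like an artifact; activity up
to 60 deg/min; position between 5° and 70°. Each channel mixes an
independent noise realization, which is what makes the fused TAP beat any
single channel. The diary restates the generative truth; the truth series
itself is the scoring reference.

What the generator does **not** emulate: ultradian sleep structure and
brief nocturnal awakenings, thermoregulatory transients (warm showers,
ambient exposure), diary misreporting, non-wear gaps, and between-subject
chronotype variation in phase. Passing validation therefore shows the
estimators and the fusion logic are correct and that CFI responds to
noise and instability as designed — not that the reported agreement rates
transfer quantitatively to human cohorts.

## Numerical choices and problem sizes

Percentiles interpolate linearly between order statistics. Window-mean
ties are detected at 1e-12 absolute tolerance. Angle computations clip
cosines into [−1, 1] before arccos; precision near parallel vectors is
~1e-5 degrees. CSV writers emit `repr` floats so read(write(x)) is
bit-exact (readers use round-trip float parsing). Validation runs use
7-day, 144-epoch/day series and cohorts of 8–20 subjects — sizes at which
every statistic is stable to the tolerances asserted, while the full test
suite completes in seconds. The frozen Monte-Carlo reference for IS of a
pattern-plus-equal-noise week (0.568) was computed with 20,000 replicates
of an independent loop-based implementation of the defining sums.

## Known limitations

- IS/IV depend on the binning choice; cross-study comparisons must fix it.
- Percentile normalization makes RA scale-dependent by design; RA values
  are comparable only between identically normalized series.
- The instability parameterization (per-boundary uniform jitter totalling
  X% of the period) and the noise-mixing convention are one reasonable
  reading of "X% instability/noise"; other simulators may scale
  differently, so only qualitative trends should be compared.
- Body position cannot distinguish arm-up from arm-down postures, and the
  tilt interpretation degrades during sustained dynamic acceleration.
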