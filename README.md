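# circatap

Ambulatory assessment of human circadian-system status from three
simultaneous wrist/arm recordings: skin **T**emperature, motor **A**ctivity
and body **P**osition.

Clinicians and chronobiologists who monitor people under free-living
conditions face a masking problem: every single marker rhythm (actimetry,
skin or core temperature, posture) is distorted by its own artifacts —
sensor removal looks like sleep onset, a bed partner's movements look like
wake, ambient temperature masks vasomotor rhythms. `circatap` implements an
integrated variable, **TAP**, that fuses the three channels so that their
independent artifacts average out, plus a single-number **Circadian
Function Index (CFI)** for scoring circadian robustness, and a simulation
framework to validate both.

## The method

Each channel is recorded for about a week (temperature every 10 min; a
3-axis ±3 g arm accelerometer every 30 s, from which motor activity is the
inter-sample angular displacement summed per 10-min epoch and expressed in
deg/min, and body position is the tilt of the device X-axis over the
horizontal plane, 0° lying – 90° upright). After artifact filtering and
alignment on the common 10-min grid, each channel is normalized per
subject by its 5th/95th percentiles and clipped to [0, 1]; temperature —
high during rest — is inverted. TAP is the epoch-wise mean of the three
normalized series: 0 = complete rest and sleep, 1 = high arousal and
movement.

Rhythm quality is quantified with the classical non-parametric statistics
(p time-of-day bins per day, n retained bins, x̄ₕ the across-days mean of
bin h):

- **IS** (interdaily stability) `IS = n Σₕ(x̄ₕ − x̄)² / (p Σᵢ(xᵢ − x̄)²)` —
  1 when the rhythm repeats exactly day after day, →0 for noise;
- **IV** (intradaily variability) `IV = n Σᵢ(xᵢ − xᵢ₋₁)² / ((n−1) Σᵢ(xᵢ − x̄)²)`
  — ≈0 for a smooth sinusoid, ≈2 for white noise;
- **L5 / M10**: midpoint clock times of the lowest 5 and highest 10
  consecutive hours of the mean 24-h waveform, with mean values VL5/VM10;
- **RA** (relative amplitude) `RA = (VM10 − VL5)/(VM10 + VL5)`;
- **CFI** `= (IS + clip(1 − IV/2, 0, 1) + RA)/3` ∈ [0, 1]: 0 = no
  circadian rhythmicity, 1 = a robust rhythm.

Rest/wake scoring thresholds each normalized series: value ≤ threshold →
rest (1), else wake (0). Thresholds are calibrated by exhaustive scan
against sleep-diary epochs on a subset of subjects and averaged;
validation reports sensitivity, specificity and agreement (plus PPV),
Pearson waveform correlations against diary rest probability, χ² on
contingency counts, and the Fisher r-to-z two-correlation test.

The simulator generates TAP-like series as a square (or sinusoidal) daily
pattern — activity phase 66% of the day — convexly mixed with 1/f fractal
noise (0–100%) and with per-day jitter of the phase boundaries
("rest-activity instability"), as well as complete synthetic subjects
(temperature/activity/position channels, diary, ground-truth rest state)
for end-to-end validation without any real recordings.

## Worked example

Simulate a small cohort at 30% noise, analyze one subject, then calibrate
and validate rest/wake scoring:

```bash
circatap simulate --subjects 2 --noise 30 --seed 42 --out demo
circatap analyze --temperature demo/s00_temperature.csv \
    --activity demo/s00_activity.csv --position demo/s00_position.csv \
    --subject-id s00 --out report
```

prints `TAP CFI for s00: 0.842` and writes `report/s00_nonparametric.tsv`:

```
variable  IS      IV      RA      L5     M10    VL5     VM10    CFI
T         0.8804  0.3394  0.7039  05:30  13:20  0.1428  0.8219  0.8049
A         0.9002  0.3194  0.7171  05:40  18:50  0.1386  0.8413  0.8192
P         0.9168  0.3479  0.7536  02:40  19:00  0.1211  0.8616  0.8322
TAP       0.9702  0.3171  0.7144  05:30  18:50  0.1397  0.8384  0.8420
```

TAP's interdaily stability (0.97) exceeds every single channel's because
their independent noise averages out; L5 falls in the middle of the
generated nocturnal rest phase. Scoring the cohort:

```bash
circatap score --subjects 8 --noise 30 --calib-n 4 --seed 42 --out scores
```

```
T:   thr=0.48 sens=0.977 spec=0.988 agree=0.984
A:   thr=0.45 sens=0.977 spec=0.997 agree=0.990
P:   thr=0.48 sens=0.989 spec=0.992 agree=0.991
TAP: thr=0.39 sens=0.995 spec=1.000 agree=0.998
```

The integrated variable beats each single channel on all three rates —
the central claim the simulation framework is built to test.

Library use mirrors the CLI:

```python
from circatap import SimulationConfig, recording_tap, summarize, synth_subject

sub = synth_subject(SimulationConfig(noise_pct=30, seed=1))
tap = recording_tap(sub.recording)
print(summarize(tap.series).CFI)
```

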