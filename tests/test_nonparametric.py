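"""Non-parametric circadian statistics against independent brute-force
oracles and their published limiting values."""

import numpy as np
import pytest

from circatap import (circadian_function_index, group_waveform, interdaily_stability,
                      intradaily_variability, l5_m10, mean_waveform, relative_amplitude,
                      summarize)
from circatap.nonparametric import MeanWaveform

from conftest import make_series

# --- independent oracles: plain-loop evaluations of the defining sums -----


def oracle_is(x, p):
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = n * sum((np.mean([x[d * p + h] for d in range(n // p)]) - xbar) ** 2
                  for h in range(p))
    den = p * sum((xi - xbar) ** 2 for xi in x)
    return num / den


def oracle_iv(x):
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = n * sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    den = (n - 1) * sum((xi - xbar) ** 2 for xi in x)
    return num / den


def oracle_l5_m10(values, bin_step):
    best = {}
    n = len(values)
    for width_s, key, pick in ((5 * 3600, "l5", min), (10 * 3600, "m10", max)):
        w = int(round(width_s / bin_step))
        means = [np.mean([values[(s + i) % n] for i in range(w)]) for s in range(n)]
        target = pick(means)
        start = min(s for s in range(n) if abs(means[s] - target) < 1e-12)
        best[key] = ((start * bin_step + width_s / 2) % 86400, means[start])
    return best["l5"], best["m10"]


class TestInterdailyStability:
    def test_exact_repetition_is_one(self, hourly_week_pattern):
        assert interdaily_stability(hourly_week_pattern) == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_near_zero(self, rng):
        s = make_series(rng.standard_normal(24 * 200), step=3600)
        # expectation ~ 1/days; frozen Monte-Carlo value 0.0048 (sd 0.0015)
        assert interdaily_stability(s) < 0.01

    def test_pattern_plus_equal_noise_matches_monte_carlo_expectation(self, rng):
        # frozen oracle: E[IS] = 0.568 (20k-replicate MC, per-replicate sd 0.045)
        day = np.sin(2 * np.pi * np.arange(24) / 24)
        day /= day.std()
        vals = [interdaily_stability(make_series(np.tile(day, 7)
                                                 + rng.standard_normal(24 * 7), step=3600))
                for _ in range(200)]
        sem = 0.045 / np.sqrt(200)
        assert np.mean(vals) == pytest.approx(0.568, abs=4 * sem + 0.002)

    def test_affine_invariance(self, hourly_week_pattern, rng):
        noisy = hourly_week_pattern.with_values(
            hourly_week_pattern.values + 0.3 * rng.standard_normal(24 * 7))
        a = interdaily_stability(noisy)
        b = interdaily_stability(noisy.with_values(5.0 * noisy.values - 3.0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError):
            interdaily_stability(make_series(np.ones(24 * 7), step=3600))


class TestIntradailyVariability:
    def test_gaussian_noise_near_two(self, rng):
        s = make_series(rng.standard_normal(10_000), step=600)
        assert intradaily_variability(s, bin_step=None) == pytest.approx(2.0, abs=0.06)

    def test_sinusoid_closed_form(self):
        # analytic: IV -> 2(1 - cos(2*pi/p)) for a sampled sinusoid
        for p in (1440, 24):
            x = np.cos(2 * np.pi * np.arange(p * 7) / p)
            s = make_series(x, step=86400 / p)
            iv = intradaily_variability(s, bin_step=None)
            assert iv == pytest.approx(2 * (1 - np.cos(2 * np.pi / p)), rel=0.01)

    def test_sawtooth_matches_brute_force(self):
        saw = np.arange(48) % 12
        s = make_series(saw, step=1800)
        got = intradaily_variability(s, bin_step=None)
        assert got == pytest.approx(0.7266775777414075, abs=1e-12)
        assert got == pytest.approx(oracle_iv(saw), abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(500)
        a = intradaily_variability(make_series(x), bin_step=None)
        b = intradaily_variability(make_series(-2.0 * x + 7), bin_step=None)
        assert a == pytest.approx(b, abs=1e-12)


class TestOracleEquivalence:
    def test_is_iv_l5_m10_match_brute_force_on_random_series(self, rng):
        """100 randomized small series: package vs defining-sum loops to 1e-12."""
        for _ in range(100):
            p = int(rng.choice([12, 24]))
            days = int(rng.integers(2, 8))
            x = rng.uniform(0, 1, p * days)
            step = 86400 / p
            s = make_series(x, step=step)
            assert interdaily_stability(s, bin_step=step) == pytest.approx(
                oracle_is(x, p), abs=1e-12)
            assert intradaily_variability(s, bin_step=None) == pytest.approx(
                oracle_iv(x), abs=1e-12)
            wf = mean_waveform(s)
            (l5m, vl5e), (m10m, vm10e) = oracle_l5_m10(wf.values, step)
            l5_mid, vl5, m10_mid, vm10 = l5_m10(wf)
            assert (l5_mid, m10_mid) == (pytest.approx(l5m), pytest.approx(m10m))
            assert vl5 == pytest.approx(vl5e, abs=1e-12)
            assert vm10 == pytest.approx(vm10e, abs=1e-12)
            assert relative_amplitude(vl5, vm10) == pytest.approx(
                (vm10e - vl5e) / (vm10e + vl5e), abs=1e-12)


class TestL5M10:
    def test_square_wave_geometry(self):
        # 0 during 00:00-08:00, 1 during 08:00-24:00
        vals = np.concatenate([np.zeros(48), np.ones(96)])
        wf = MeanWaveform(600, vals, np.zeros(144), n_days=1)
        l5_mid, vl5, m10_mid, vm10 = l5_m10(wf)
        assert l5_mid == pytest.approx(4 * 3600)  # 04:00
        assert vl5 == pytest.approx(0.0, abs=1e-12)
        assert vm10 == pytest.approx(1.0, abs=1e-12)
        assert 8 * 3600 < m10_mid < 24 * 3600

    def test_constant_waveform_has_zero_amplitude(self):
        wf = MeanWaveform(600, np.full(144, 0.3), np.zeros(144), n_days=1)
        _, vl5, _, vm10 = l5_m10(wf)
        assert vl5 == pytest.approx(0.3, abs=1e-12)
        assert vm10 == pytest.approx(0.3, abs=1e-12)
        assert relative_amplitude(vl5, vm10) == pytest.approx(0.0, abs=1e-12)

    def test_cosine_minimum_centers_l5(self):
        t = np.arange(144) * 600
        vals = 1 - np.cos(2 * np.pi * (t - 4 * 3600) / 86400)  # min at 04:00
        wf = MeanWaveform(600, vals, np.zeros(144), n_days=1)
        l5_mid, _, m10_mid, _ = l5_m10(wf)
        assert l5_mid == pytest.approx(4 * 3600, abs=600)
        assert m10_mid == pytest.approx(16 * 3600, abs=600)

    def test_day_shift_invariance(self, rng):
        x = rng.uniform(0, 1, 144 * 4)
        s = make_series(x, step=600)
        shifted = make_series(np.roll(x, 144), step=600)
        assert l5_m10(mean_waveform(s)) == pytest.approx(l5_m10(mean_waveform(shifted)))


class TestRelativeAmplitudeAndCFI:
    @pytest.mark.parametrize("vl5, vm10, expected", [
        (0.25, 0.75, 0.5), (0.4, 0.4, 0.0), (0.0, 1.0, 1.0), (0.0, 0.0, 0.0),
    ])
    def test_ra_values(self, vl5, vm10, expected):
        assert relative_amplitude(vl5, vm10) == pytest.approx(expected)

    def test_ra_rejects_negative(self):
        with pytest.raises(ValueError):
            relative_amplitude(-0.1, 0.5)

    @pytest.mark.parametrize("is_, iv, ra, expected", [
        (1.0, 0.0, 1.0, 1.0),
        (0.0, 2.0, 0.0, 0.0),
        (0.6, 0.6, 0.6, (0.6 + 0.7 + 0.6) / 3),
        (0.5, 3.0, 0.5, (0.5 + 0.0 + 0.5) / 3),  # IV > 2 clips to 0
    ])
    def test_cfi_values(self, is_, iv, ra, expected):
        assert circadian_function_index(is_, iv, ra) == pytest.approx(expected, abs=1e-12)

    def test_cfi_monotone(self):
        base = circadian_function_index(0.5, 1.0, 0.5)
        assert circadian_function_index(0.6, 1.0, 0.5) > base
        assert circadian_function_index(0.5, 1.2, 0.5) < base
        assert circadian_function_index(0.5, 1.0, 0.6) > base

    def test_cfi_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            circadian_function_index(1.5, 1.0, 0.5)


class TestMeanWaveform:
    def test_identical_days_reproduce_day_with_zero_sem(self, hourly_week_pattern):
        wf = mean_waveform(hourly_week_pattern)
        np.testing.assert_allclose(wf.values, hourly_week_pattern.values[:24])
        np.testing.assert_allclose(wf.sem, 0.0, atol=1e-12)
        assert wf.n_days == 7

    def test_single_day_is_itself(self, rng):
        x = rng.uniform(0, 1, 144)
        wf = mean_waveform(make_series(x, step=600))
        np.testing.assert_allclose(wf.values, x)

    def test_two_day_bin_statistics(self):
        a = 3.0
        x = np.concatenate([np.full(24, a), np.full(24, a + 2)])
        wf = mean_waveform(make_series(x, step=3600))
        np.testing.assert_allclose(wf.values, a + 1)
        np.testing.assert_allclose(wf.sem, 1.0)  # sd sqrt(2) over sqrt(2)

    def test_group_waveform_averages_subjects(self, rng):
        wfs = [mean_waveform(make_series(rng.uniform(0, 1, 144 * 2), step=600))
               for _ in range(5)]
        g = group_waveform(wfs)
        np.testing.assert_allclose(g.values, np.mean([w.values for w in wfs], axis=0))


def test_summarize_bundles_consistent_fields(rng):
    from circatap import simulate_tap, SimulationConfig
    s = simulate_tap(SimulationConfig(noise_pct=30, seed=5))
    out = summarize(s)
    assert out.RA == pytest.approx((out.VM10 - out.VL5) / (out.VM10 + out.VL5))
    expected_cfi = (min(out.IS, 1) + np.clip(1 - out.IV / 2, 0, 1) + out.RA) / 3
    assert out.CFI == pytest.approx(expected_cfi, abs=1e-12)
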