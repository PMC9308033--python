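"""Morse wavelet transform, band power, second-order circadian modulation."""

import numpy as np
import pytest

import telemvar as tv
from telemvar.spectra import (
    CIRCADIAN_BAND,
    ULTRADIAN_BAND,
    BandPowerSeries,
    MorseParams,
    PeriodGrid,
)

from conftest import make_series

VOICE = 2 ** (1 / 16)


def cosine(period, n_days=14, amp=1.0):
    t = np.arange(n_days * 1440.0)
    return amp * np.cos(2 * np.pi * t / period)


def recovered_peak_period(wpm):
    """Period with the largest COI-excluded time-averaged power."""
    valid = ~wpm.coi_mask
    avg = np.array([
        wpm.power[i][valid[i]].mean() if valid[i].any() else 0.0
        for i in range(len(wpm.periods_min))
    ])
    return wpm.periods_min[np.argmax(avg)]


class TestMorseCwt:
    @pytest.mark.parametrize("period", [60.0, 120.0, 480.0, 1440.0])
    def test_peak_period_recovery_within_one_voice(self, period):
        wpm = tv.morse_cwt(cosine(period))
        assert recovered_peak_period(wpm) == pytest.approx(period, rel=VOICE - 1)

    def test_power_scales_with_amplitude_squared(self):
        w1 = tv.morse_cwt(cosine(120.0, n_days=7))
        w2 = tv.morse_cwt(cosine(120.0, n_days=7, amp=2.0))
        assert np.allclose(w2.power, 4.0 * w1.power, rtol=1e-9, atol=1e-12)

    def test_superposed_cosines_peak_in_both_bands(self):
        x = cosine(120.0) + cosine(1440.0)
        wpm = tv.morse_cwt(x)
        valid = ~wpm.coi_mask
        avg = np.array([
            wpm.power[i][valid[i]].mean() if valid[i].any() else 0.0
            for i in range(len(wpm.periods_min))
        ])
        in_ult = (wpm.periods_min >= 60) & (wpm.periods_min <= 180)
        in_circ = (wpm.periods_min >= 1380) & (wpm.periods_min <= 1500)
        # strong power in both bands, weak in between
        between = (wpm.periods_min > 300) & (wpm.periods_min < 900)
        assert avg[in_ult].max() > 10 * avg[between].max()
        assert avg[in_circ].max() > 10 * avg[between].max()

    def test_unit_cosine_peak_power_near_one(self):
        wpm = tv.morse_cwt(cosine(1440.0))
        i = np.argmin(np.abs(wpm.periods_min - 1440.0))
        mid = wpm.power[i][~wpm.coi_mask[i]]
        assert mid.max() == pytest.approx(1.0, rel=0.05)

    def test_record_shorter_than_two_longest_periods_rejected(self):
        with pytest.raises(ValueError, match="short"):
            tv.morse_cwt(np.zeros(1440), PeriodGrid(30, 2160))

    def test_invalid_morse_params_rejected(self):
        with pytest.raises(ValueError):
            MorseParams(beta=0.0)


class TestBandMaxPower:
    def test_single_period_grid_returns_that_row(self):
        grid = PeriodGrid(119.0, 121.0, voices_per_octave=64)
        wpm = tv.morse_cwt(cosine(120.0, n_days=2), grid)
        bps = tv.band_max_power(wpm, 119.0, 121.0)
        assert np.allclose(
            bps.per_minute_max_power, wpm.power.max(axis=0)
        )

    def test_band_power_near_constant_mid_record_for_pure_cosine(self):
        wpm = tv.morse_cwt(cosine(120.0, n_days=7))
        bps = tv.band_max_power(wpm, *ULTRADIAN_BAND)
        mid = bps.per_minute_max_power[bps.valid]
        assert mid.min() > 0
        assert mid.std() / mid.mean() < 0.05

    def test_zero_signal_gives_zero_band_power(self):
        wpm = tv.morse_cwt(np.zeros(7 * 1440))
        bps = tv.band_max_power(wpm, *ULTRADIAN_BAND)
        assert np.allclose(bps.per_minute_max_power, 0.0)

    def test_empty_band_rejected(self):
        wpm = tv.morse_cwt(cosine(120.0, n_days=7))
        with pytest.raises(ValueError):
            tv.band_max_power(wpm, 2200.0, 2400.0)


class TestSecondOrder:
    def test_modulated_animal_has_greater_second_order_power(self):
        grid = PeriodGrid(60, 180)
        second = PeriodGrid(1200, 1700)
        medians = {}
        for depth in (0.0, 0.8):
            spec = tv.AnimalSpec(
                sex="male", baseline_level=36.9, circ_amp=0.0, ult_amp=0.4,
                ult_mod_depth=depth, ult_phase_jitter_sd=0.02, noise_sd=0.1,
            )
            s = tv.simulate_animal(spec, n_days=5, seed=21)
            bps = tv.circadian_modulation_of_ultradian(
                s, grid, second_grid=second
            )
            medians[depth] = tv.band_power_summary(bps)["median"]
        assert medians[0.8] > medians[0.0]

    def test_second_order_monotone_in_modulation_depth(self):
        from scipy.stats import spearmanr

        grid = PeriodGrid(60, 180)
        second = PeriodGrid(1200, 1700)
        depths = [0.0, 0.25, 0.5, 0.75, 1.0]
        for seed in (1, 2, 3):
            medians = []
            for depth in depths:
                spec = tv.AnimalSpec(
                    sex="male", baseline_level=36.9, circ_amp=0.0,
                    ult_amp=0.4, ult_mod_depth=depth,
                    ult_phase_jitter_sd=0.02, noise_sd=0.1,
                )
                s = tv.simulate_animal(spec, n_days=5, seed=seed)
                bps = tv.circadian_modulation_of_ultradian(
                    s, grid, second_grid=second
                )
                medians.append(tv.band_power_summary(bps)["median"])
            rho = spearmanr(depths, medians).statistic
            assert rho == pytest.approx(1.0)

    def test_zero_signal_gives_zero_second_order(self):
        bps = tv.circadian_modulation_of_ultradian(np.zeros(7 * 1440))
        assert np.allclose(bps.per_minute_max_power, 0.0)


class TestBandPowerSummary:
    def test_constant_series(self):
        bps = BandPowerSeries("A", ULTRADIAN_BAND, np.full(100, 3.0), "first")
        s = tv.band_power_summary(bps)
        assert s["mean"] == 3.0 and s["median"] == 3.0

    def test_mean_median_split(self):
        bps = BandPowerSeries("A", ULTRADIAN_BAND,
                              np.array([0.0, 0.0, 0.0, 4.0]), "first")
        s = tv.band_power_summary(bps)
        assert s["mean"] == 1.0 and s["median"] == 0.0

    def test_matches_brute_force_on_valid_minutes(self):
        rng = np.random.default_rng(4)
        values = rng.random(500)
        valid = rng.random(500) > 0.3
        bps = BandPowerSeries("A", ULTRADIAN_BAND, values, "first", valid=valid)
        s = tv.band_power_summary(bps)
        assert s["mean"] == pytest.approx(values[valid].mean())
        assert s["median"] == pytest.approx(np.median(values[valid]))
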