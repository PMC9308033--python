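"""Baselines, the error statistic, cumulative curves, mean-day error."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import telemvar as tv
from telemvar.baseline import DayProfile, SD_EPSILON
from telemvar.preprocessing import CohortMatrix

from conftest import make_series


def matrix_of(values, sexes=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return CohortMatrix(
        animal_ids=tuple(f"A{i}" for i in range(n)),
        sexes=tuple(sexes or ["male"] * n),
        values=values, arrangement="raw", signal_kind="temperature",
    )


class TestBaselines:
    def test_static_matches_direct_formula(self):
        m = matrix_of([[1, 1], [3, 3]])
        b = tv.static_baseline(m)
        flat = np.array([1, 1, 3, 3], dtype=float)
        assert b.mean == pytest.approx(2.0)
        assert b.sd == pytest.approx(np.std(flat, ddof=1))

    def test_constant_matrix_sd_floored_and_flagged(self):
        b = tv.static_baseline(matrix_of(np.full((3, 4), 5.0)))
        assert b.sd == SD_EPSILON
        assert b.flagged

    def test_single_row_static_equals_row_stats(self):
        row = np.array([1.0, 2.0, 4.0, 8.0])
        b = tv.static_baseline(matrix_of(row[None, :]))
        assert b.mean == pytest.approx(row.mean())
        assert b.sd == pytest.approx(np.std(row, ddof=1))

    def test_dynamic_matches_columnwise_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 100))
        b = tv.dynamic_baseline(matrix_of(values))
        assert np.allclose(b.means, values.mean(axis=0))
        assert np.allclose(b.sds, values.std(axis=0, ddof=1))

    def test_two_row_means(self):
        b = tv.dynamic_baseline(matrix_of([[0.0] * 5, [2.0] * 5]))
        assert np.allclose(b.means, 1.0)

    def test_dynamic_single_row_rejected(self):
        with pytest.raises(ValueError):
            tv.dynamic_baseline(matrix_of(np.zeros((1, 10))))


class TestErrorValue:
    def test_within_one_sd_scores_zero(self):
        assert tv.error_value(37.2, 37.0, 0.4) == 0.0

    def test_three_sd_scores_two(self):
        assert tv.error_value(38.2, 37.0, 0.4) == pytest.approx(2.0)

    def test_symmetric_below_mean(self):
        assert tv.error_value(35.8, 37.0, 0.4) == pytest.approx(2.0)

    @given(
        x=st.floats(-100, 100), m=st.floats(-100, 100),
        s=st.floats(0.01, 10), a=st.floats(0.01, 50), b=st.floats(-100, 100),
    )
    @settings(deadline=None, max_examples=200)
    def test_translation_and_scale_equivariance(self, x, m, s, a, b):
        left = tv.error_value(a * x + b, a * m + b, a * s)
        right = tv.error_value(x, m, s)
        assert left == pytest.approx(right, rel=1e-9, abs=1e-9)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            tv.error_value(1.0, 0.0, 0.0)


class TestErrorCurve:
    def test_series_matching_dynamic_means_scores_zero(self):
        means = np.linspace(36, 38, 50)
        baseline = tv.DynamicBaseline(means=means, sds=np.full(50, 0.3))
        curve = tv.error_curve(make_series(means), baseline)
        assert np.all(curve.per_minute_error == 0)
        assert curve.final == 0

    def test_cumulative_is_running_sum(self):
        baseline = tv.StaticBaseline(mean=0.0, sd=1.0)
        curve = tv.error_curve(make_series([0.0, 2.0, 3.0]), baseline)
        assert np.allclose(curve.per_minute_error, [0.0, 1.0, 2.0])
        assert np.allclose(curve.cumulative, [0.0, 1.0, 3.0])
        assert curve.cumulative[0] == curve.per_minute_error[0]

    def test_static_final_matches_brute_force_sum(self):
        rng = np.random.default_rng(1)
        values = 37 + rng.normal(size=400)
        baseline = tv.StaticBaseline(mean=37.0, sd=0.5)
        curve = tv.error_curve(make_series(values), baseline)
        expected = sum(
            max(0.0, abs(v - 37.0) / 0.5 - 1.0) for v in values
        )
        assert curve.final == pytest.approx(expected)
        assert np.all(np.diff(curve.cumulative) >= 0)

    def test_common_unit_rescales_dynamic_curve(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=100)
        baseline = tv.DynamicBaseline(
            means=np.zeros(100), sds=np.full(100, 0.5)
        )
        in_own_sd = tv.error_curve(make_series(values), baseline)
        in_unit = tv.error_curve(make_series(values), baseline, unit_sd=1.0)
        # constant per-minute SD: unit conversion is an overall rescale
        assert np.allclose(in_unit.per_minute_error,
                           in_own_sd.per_minute_error * 0.5)

    def test_length_mismatch_rejected(self):
        baseline = tv.DynamicBaseline(means=np.zeros(10), sds=np.ones(10))
        with pytest.raises(ValueError):
            tv.error_curve(make_series(np.zeros(11)), baseline)


class TestMeanDayProfile:
    def test_jitter_free_animal_has_zero_profile_sd(self, quiet_male):
        s = tv.simulate_animal(quiet_male, n_days=3, seed=0)
        profile = tv.mean_day_profile(s)
        assert np.allclose(profile.minute_of_day_sds, 0.0, atol=1e-9)

    def test_shifted_second_day_averages(self):
        day1 = np.linspace(0, 10, 1440)
        s = make_series(np.concatenate([day1, day1 + 1.0]))
        profile = tv.mean_day_profile(s)
        assert np.allclose(profile.minute_of_day_means, day1 + 0.5)

    def test_matches_fold_by_1440_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=4 * 1440)
        profile = tv.mean_day_profile(make_series(values))
        folded = values.reshape(4, 1440)
        assert np.allclose(profile.minute_of_day_means, folded.mean(axis=0))
        assert np.allclose(profile.minute_of_day_sds, folded.std(axis=0, ddof=1))

    def test_partial_days_rejected(self):
        with pytest.raises(ValueError):
            tv.mean_day_profile(make_series(np.zeros(2000)))


class TestWithinDayError:
    def test_perfectly_repeating_animal_scores_zero(self, quiet_male):
        s = tv.simulate_animal(quiet_male, n_days=3, seed=0)
        curve = tv.within_day_error(s, tv.mean_day_profile(s))
        assert curve.final == 0.0

    def test_day_displaced_three_profile_sd_scores_two_per_minute(self):
        means = np.full(1440, 37.0)
        sds = np.full(1440, 0.2)
        profile = DayProfile("A00", means, sds)
        day = means + 3 * sds
        s = make_series(np.concatenate([means, day]))
        curve = tv.within_day_error(s, profile)
        assert curve.day_subtotals[0] == 0.0
        assert curve.day_subtotals[1] == pytest.approx(2.0 * 1440)

    def test_profile_animal_mismatch_rejected(self):
        profile = DayProfile("OTHER", np.zeros(1440), np.ones(1440))
        with pytest.raises(ValueError, match="OTHER"):
            tv.within_day_error(make_series(np.zeros(1440)), profile)


class TestNormalizationAndReduction:
    def test_normalize_by_individual_sd(self):
        s = make_series([0.0, 2.0, 4.0, 6.0])  # sd ~ 2.58
        assert tv.normalize_by_individual_sd(10.0, s) == pytest.approx(10.0 / s.sd())
        assert tv.normalize_by_individual_sd(0.0, s) == 0.0

    def test_error_reduction_percent(self):
        assert tv.error_reduction_percent(90.0, 60.0) == pytest.approx(100 / 3)
        assert tv.error_reduction_percent(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            tv.error_reduction_percent(0.0, 1.0)


class TestStructuredVariance:
    def test_shared_circadian_structure_reduces_dynamic_error(self):
        """Any shared circadian amplitude makes cohort-mean dynamic error
        lower than static error (structured variance is explained away)."""
        male, female = tv.default_sex_profiles("temperature")
        cfg = tv.CohortConfig(n_males=4, n_females=4,
                              signal_kind="temperature", master_seed=11, n_days=3)
        cleaned = [tv.clean(s) for s in tv.simulate_cohort(cfg)]
        matrix = tv.align_to_estrous(cleaned)
        static = tv.static_baseline(matrix)
        dynamic = tv.dynamic_baseline(matrix)
        finals_static, finals_dynamic = [], []
        for i in range(matrix.n_animals):
            row = matrix.row_series(i)
            finals_static.append(tv.error_curve(row, static).final)
            finals_dynamic.append(
                tv.error_curve(row, dynamic, unit_sd=static.sd).final
            )
        assert np.mean(finals_dynamic) < np.mean(finals_static)
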