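"""Impulse-process realisation: counts, timings, trains and rasterisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import allostasim as al
from allostasim.impulses import NIGHT, WORK


def _person(lambda_work=16.0, lambda_night=42.0, rho_c=0.52, pid=0):
    return al.PersonParams(
        person_id=pid, lambda_work=lambda_work, lambda_night=lambda_night, rho_c=rho_c
    )


class TestScaledWorkRate:
    @pytest.mark.parametrize(
        "lam, hours, expected",
        [(16.0, 8.0, 16.0), (16.0, 4.0, 8.0), (24.0, 40.0 / 3.0, 40.0)],
    )
    def test_linear_scaling(self, lam, hours, expected):
        assert al.scaled_work_rate(lam, hours) == pytest.approx(expected)

    def test_nonpositive_hours_rejected(self):
        with pytest.raises(ValueError):
            al.scaled_work_rate(10.0, 0.0)


class TestDailyCount:
    def test_zero_rate(self, rng):
        assert al.daily_count(0.0, rng) == 0

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            al.daily_count(-1.0, rng)

    def test_poisson_moments(self, rng):
        draws = np.array([al.daily_count(42.0, rng) for _ in range(10_000)])
        assert abs(draws.mean() - 42.0) < 0.2
        assert abs(draws.var() - 42.0) < 2.0


class TestImpulseTimes:
    def test_empty_draws(self, rng):
        assert len(al.draw_night_times(0, 7.0, rng)) == 0
        assert len(al.draw_work_times(0, (8.5, 16.5), rng)) == 0

    def test_night_offsets_exponential(self, rng):
        onsets = al.draw_night_times(10_000, 7.0, rng)
        assert np.all(onsets < 7.0)
        assert abs((7.0 - onsets).mean() - 1.0) < 0.03  # Exp(1) mean oracle

    def test_work_times_uniform_over_window(self, rng):
        onsets = al.draw_work_times(10_000, (8.5, 16.5), rng)
        assert np.all((onsets >= 8.5) & (onsets < 16.5))
        assert abs(onsets.mean() - 12.5) < 5 / 60  # uniform midpoint oracle

    def test_work_times_without_window_rejected(self, rng):
        with pytest.raises(ValueError):
            al.draw_work_times(3, None, rng)


class TestBuildTrain:
    def test_no_work_rate_gives_pure_night_train(self, rng):
        train = al.build_train(_person(lambda_work=0.0), al.standard_week(), 10, rng)
        assert train.count(WORK) == 0
        assert train.count(NIGHT) == len(train)

    def test_weekends_free_of_work(self, rng):
        train = al.build_train(_person(lambda_work=30.0), al.standard_week(), 28, rng)
        work_onsets = train.onsets[train.kinds == WORK]
        weekdays = (np.floor(work_onsets / 24.0).astype(int)) % 7
        assert np.all(weekdays <= 4)
        # every work impulse sits inside the daily 08:30-16:30 window
        clock = work_onsets % 24.0
        assert np.all((clock >= 8.5) & (clock < 16.5))

    def test_night_total_matches_poisson_sum(self, rng):
        train = al.build_train(_person(lambda_night=42.0), al.standard_week(), 200, rng)
        total = train.count(NIGHT)
        assert abs(total - 8400) < 3 * np.sqrt(8400)

    def test_sorted_by_onset(self, rng):
        train = al.build_train(_person(), al.standard_week(), 5, rng)
        assert np.all(np.diff(train.onsets) >= 0)

    def test_anticipation_scaling_identity_at_reference_day(self):
        person = _person(lambda_work=20.0, lambda_night=30.0)
        t1 = al.build_train(person, al.standard_week(), 10, np.random.default_rng(3))
        t2 = al.build_train(
            person, al.standard_week(), 10, np.random.default_rng(3),
            anticipation_scaling=True,
        )
        assert np.array_equal(t1.onsets, t2.onsets)

    def test_anticipation_scaling_tracks_day_length(self):
        # 16-hour days double the work-rate component of the night rate:
        # lambda_night 30 -> 30 + 20*(16-8)/8 = 50 expected nightly impulses
        person = _person(lambda_work=20.0, lambda_night=30.0)
        cfg = al.WorkweekConfig(name="long", working_days=frozenset({0, 1, 2}), hours_per_day=16.0, work_start=7.0)
        counts = []
        for s in range(200):
            train = al.build_train(person, cfg, 5, np.random.default_rng(s), anticipation_scaling=True)
            counts.append(train.count(NIGHT))
        mean_nightly = np.mean(counts) / 5
        assert abs(mean_nightly - 50.0) < 3 * np.sqrt(50.0 / len(counts) / 5)

    def test_csv_round_trip(self, rng, tmp_path):
        train = al.build_train(_person(), al.standard_week(), 3, rng)
        path = tmp_path / "train.csv"
        train.to_csv(path)
        import pandas as pd

        back = al.ImpulseTrain.from_frame(pd.read_csv(path))
        assert np.allclose(back.onsets, train.onsets)
        assert list(back.kinds) == list(train.kinds)


class TestWeeklyWorkInvariance:
    def test_equal_weekly_hours_give_equal_expected_counts(self):
        """Day-length scaling keeps the expected weekly work-impulse count
        invariant across layouts with equal weekly hours."""
        person = _person(lambda_work=24.0)
        days = 280  # 40 full weeks
        expected_total = 24.0 / 8.0 * 40.0 * (days / 7)
        totals = []
        for cfg in al.standard_configurations(40.0):
            train = al.build_train(person, cfg, days, np.random.default_rng(11))
            totals.append(train.count(WORK))
        sd = np.sqrt(expected_total)
        for total in totals:
            assert abs(total - expected_total) < 4 * sd


class TestRasterize:
    def test_empty_train_is_all_zero(self):
        train = al.ImpulseTrain(0, [], [])
        grid = al.rasterize(train, 0.5, 24.0)
        assert grid.shape == (48,)
        assert not grid.any()

    def test_simultaneous_impulses_add(self):
        train = al.ImpulseTrain(0, [10.2, 10.3], [NIGHT, WORK])
        grid = al.rasterize(train, 0.5, 24.0)
        assert grid[20] == 2  # floor(10.2/0.5) == floor(10.3/0.5) == 20
        assert grid.sum() == 2

    def test_single_onset_lands_in_containing_step(self):
        train = al.ImpulseTrain(0, [10.2], [WORK])
        grid = al.rasterize(train, 0.5, 24.0)
        assert grid[20] == 1 and grid.sum() == 1

    def test_preroll_grid_shifts_indices(self):
        train = al.ImpulseTrain(0, [-0.3, 10.2], [NIGHT, WORK])
        grid = al.rasterize(train, 0.5, 24.0, t_start=-24.0)
        assert grid[47] == 1  # onset just before midnight of day 0
        assert grid[48 + 20] == 1

    def test_bad_grid_rejected(self):
        train = al.ImpulseTrain(0, [], [])
        with pytest.raises(ValueError):
            al.rasterize(train, 0.5, 24.3)

    @settings(derandomize=True, max_examples=60)
    @given(
        onsets=st.lists(
            st.floats(min_value=0.0, max_value=47.9, allow_nan=False), max_size=40
        )
    )
    def test_conservation(self, onsets):
        """Every in-horizon impulse is counted exactly once."""
        train = al.ImpulseTrain(0, onsets, [NIGHT] * len(onsets))
        grid = al.rasterize(train, 0.5, 48.0)
        assert grid.sum() == len(onsets)
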