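"""Suggestion loop, performance rating, profiler, and scheduling."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from rehabcoach.glicko import LOSS, TIE, WIN, MatchOutcome, update_rating
from rehabcoach.recommend import (
    INITIAL_DEVIATION,
    INITIAL_RATING,
    INITIAL_VOLATILITY,
    PerformanceRecord,
    _Registry,
    force_suggest,
    next_due,
    profiler_check,
    register_user,
    report_performance,
    suggest,
)

FOUR = ["arm raises", "mini squats", "step up", "chest stretch"]


def fresh_user(allowed=FOUR, interval=24):
    return register_user("u1", allowed, interval=interval, _registry=_Registry())


class TestRegistration:
    def test_all_exercises_start_at_base_rating(self):
        user = fresh_user()
        assert set(user.ratings) == set(FOUR)
        for state in user.ratings.values():
            assert (state.rating, state.deviation, state.volatility) == (
                INITIAL_RATING,
                INITIAL_DEVIATION,
                INITIAL_VOLATILITY,
            )
        assert user.history == [] and user.last_two == []

    def test_empty_allowed_set_rejected(self):
        with pytest.raises(ValueError):
            register_user("u2", [], _registry=_Registry())

    def test_duplicate_registration_rejected(self):
        registry = _Registry()
        register_user("u3", FOUR, _registry=registry)
        with pytest.raises(ValueError):
            register_user("u3", FOUR, _registry=registry)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            fresh_user(interval=6)


class TestSuggest:
    def test_fresh_ratings_pick_uniformly(self):
        rng = np.random.default_rng(0)
        picks = {suggest(fresh_user(), rng) for _ in range(100)}
        assert picks == set(FOUR)

    def test_never_repeats_within_window_of_two(self, rng):
        user = fresh_user()
        for i in range(200):
            blocked = list(user.last_two)
            choice = suggest(user, rng)
            assert choice not in blocked
            report_performance(user, choice, float(rng.uniform(0, 100)))

    def test_forced_pick_ignores_rating(self):
        user = fresh_user(["a", "b", "c"])
        user.last_two = ["a", "b"]
        assert suggest(user, np.random.default_rng(0)) == "c"

    def test_highest_rated_eligible_wins(self):
        user = fresh_user()
        force_suggest(user, "arm raises")
        report_performance(user, "arm raises", 90.0)  # beats all neutral refs
        assert suggest(user, np.random.default_rng(0)) != "arm raises"  # blocked
        user.last_two = []
        assert suggest(user, np.random.default_rng(0)) == "arm raises"

    def test_exhausted_pool_rejected(self):
        user = fresh_user(["a", "b"])
        user.last_two = ["a", "b"]
        with pytest.raises(ValueError):
            suggest(user, np.random.default_rng(0))


class TestReportPerformance:
    def test_first_strong_performance_raises_rating(self):
        user = fresh_user()
        force_suggest(user, "arm raises")
        report_performance(user, "arm raises", 60.0)
        assert user.ratings["arm raises"].rating > INITIAL_RATING
        assert len(user.history) == 1
        assert user.history[0] == PerformanceRecord(1, "arm raises", 60.0)

    def test_all_ties_barely_move_the_rating(self):
        user = fresh_user()
        for name in FOUR:  # seed identical references at 50
            force_suggest(user, name)
            report_performance(user, name, 50.0)
        force_suggest(user, "arm raises")
        before = user.ratings["arm raises"].rating
        report_performance(user, "arm raises", 51.0)  # within the +/-2 band of all
        assert abs(user.ratings["arm raises"].rating - before) < 1.0

    def test_matches_direct_rating_engine_computation(self):
        user = fresh_user(["a", "b", "c"])
        for name, pct in [("a", 50.0), ("b", 60.0), ("c", 40.0)]:
            force_suggest(user, name)
            report_performance(user, name, pct)
        # next: 'a' performs 50 -> b's ref 60 > 52 (loss), c's ref 40 < 48 (win)
        expected = update_rating(
            user.ratings["a"],
            [
                MatchOutcome(user.ratings["b"], LOSS),
                MatchOutcome(user.ratings["c"], WIN),
            ],
        )
        force_suggest(user, "a")
        report_performance(user, "a", 50.0)
        assert user.ratings["a"] == expected

    def test_idle_opponents_only_age(self):
        user = fresh_user()
        force_suggest(user, "arm raises")
        report_performance(user, "arm raises", 60.0)
        for name in set(FOUR) - {"arm raises"}:
            state = user.ratings[name]
            assert state.rating == INITIAL_RATING
            assert state.deviation > INITIAL_DEVIATION

    def test_strict_dominance_strictly_raises_and_vice_versa(self):
        user = fresh_user()
        for name, pct in zip(FOUR, [50.0, 55.0, 45.0, 50.0]):
            force_suggest(user, name)
            report_performance(user, name, pct)
        force_suggest(user, "arm raises")
        before = user.ratings["arm raises"].rating
        report_performance(user, "arm raises", 90.0)  # above every ref by > 2
        assert user.ratings["arm raises"].rating > before
        force_suggest(user, "mini squats")
        before = user.ratings["mini squats"].rating
        report_performance(user, "mini squats", 5.0)  # below every ref by > 2
        assert user.ratings["mini squats"].rating < before

    def test_out_of_range_or_unexpected_exercise_rejected(self):
        user = fresh_user()
        force_suggest(user, "arm raises")
        with pytest.raises(ValueError):
            report_performance(user, "arm raises", 120.0)
        with pytest.raises(ValueError):
            report_performance(user, "mini squats", 50.0)


class TestProfiler:
    @staticmethod
    def with_history(exercise, values):
        user = fresh_user()
        user.history = [
            PerformanceRecord(i + 1, exercise, v) for i, v in enumerate(values)
        ]
        return user

    def test_printed_step_up_series_flags_declining(self):
        user = self.with_history("step up", [77.2, 68.3, 70.1, 47.1, 78.6, 26.1, 10])
        report = profiler_check(user, "step up")
        assert report.flag == "declining"
        assert report.evidence[-1] == 10

    def test_continuously_low_series_flags_chronically_low(self):
        user = self.with_history("chest stretch", [18.32, 9.02])
        assert profiler_check(user, "chest stretch").flag == "chronically_low"

    def test_steady_history_raises_no_flag(self):
        user = self.with_history("arm raises", [80.0] * 6)
        assert profiler_check(user, "arm raises").flag == "none"

    def test_single_low_value_is_not_yet_chronic(self):
        user = self.with_history("arm raises", [10.0])
        assert profiler_check(user, "arm raises").flag == "none"

    def test_decline_requires_drop_below_half_of_maximum(self):
        user = self.with_history("arm raises", [80.0, 75.0, 70.0])
        assert profiler_check(user, "arm raises").flag == "none"  # 70 > 40


class TestScheduling:
    def test_before_any_trigger_due_at_registration(self):
        t0 = datetime(2020, 1, 1, 10, 0)
        user = register_user("u9", FOUR, registered_at=t0, _registry=_Registry())
        assert next_due(user) == t0

    @pytest.mark.parametrize("interval", [4, 8, 12, 24])
    def test_cadence_follows_interval(self, interval):
        t0 = datetime(2020, 1, 1, 10, 0)
        user = register_user(
            "u10", FOUR, interval=interval, registered_at=t0, _registry=_Registry()
        )
        user.last_trigger = t0
        assert next_due(user) == t0 + timedelta(hours=interval)
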