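"""Wear-time arithmetic, day summaries, valid-day rules, estimates."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import START, make_series, random_series, series_from_daily
from weartime import core
from weartime.core import (
    DEFAULT_RULES,
    PRESET_RULES,
    ValidDayRule,
    compute_wear_fraction,
    daily_summaries,
    estimate_subject,
    monthly_wear_trend,
    summarize_day,
    window_total_minutes,
)


def naive_wear_fraction(data: pd.DataFrame, start, end) -> float:
    """Independent oracle: walk the window minute by minute and count."""
    present = {
        ts: not pd.isna(hr) for ts, hr in data["heart_rate"].items()
    }
    t = pd.Timestamp(start)
    worn = total = 0
    while t < pd.Timestamp(end):
        total += 1
        if present.get(t, False):
            worn += 1
        t += pd.Timedelta(minutes=1)
    return worn / total


class TestWearFraction:
    def test_full_day_denominator_is_1440(self):
        assert window_total_minutes("2021-01-01", "2021-01-02") == 1440

    def test_full_wear_day_is_one(self):
        s = series_from_daily([1440])
        assert compute_wear_fraction(s.data, "2021-01-01", "2021-01-02") == 1.0

    def test_half_wear_day_is_half(self):
        s = series_from_daily([720])
        assert compute_wear_fraction(s.data, "2021-01-01", "2021-01-02") == 0.5

    def test_empty_window_is_error(self):
        s = series_from_daily([10])
        with pytest.raises(ValueError):
            compute_wear_fraction(s.data, "2021-01-01", "2021-01-01")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_minute_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_series(rng, study_days=2)
        start, end = "2021-01-01", "2021-01-03"
        assert compute_wear_fraction(s.data, start, end) == pytest.approx(
            naive_wear_fraction(s.data, start, end)
        )


class TestSummarizeDay:
    def test_full_day_aggregates(self):
        s = series_from_daily([1440], steps_per_worn_minute=5, hr=70)
        day = summarize_day(s.data, "s1", date(2021, 1, 1))
        assert day.wear_minutes == 1440
        assert day.total_steps == 7200
        assert day.mean_hr == 70
        assert day.wear_fraction == 1.0

    def test_zero_record_day(self):
        day = summarize_day(
            pd.DataFrame({"heart_rate": [], "steps": []}), "s1", date(2021, 1, 1)
        )
        assert day.wear_minutes == 0 and day.total_steps == 0
        assert day.mean_hr is None
        assert day.validity == {"none": True, "stepcount1000": False, "weartime80": False}

    def test_partial_day_validity_flags(self):
        # wear fraction ~0.81 with 900 total steps
        wear = int(round(0.81 * 1440))
        s = series_from_daily([wear], steps_per_worn_minute=0)
        data = s.data.copy()
        data.iloc[:900, data.columns.get_loc("steps")] = 1.0
        day = summarize_day(data, "s1", date(2021, 1, 1))
        assert day.total_steps == 900
        assert day.validity["weartime80"] is True
        assert day.validity["stepcount1000"] is False

    def test_steps_without_hr_count_toward_steps_not_wear(self):
        s = make_series(
            [("2021-01-01T08:00", 70, 10), ("2021-01-01T08:01", None, 20)]
        )
        day = summarize_day(s.data, "s1", date(2021, 1, 1))
        assert day.total_steps == 30 and day.wear_minutes == 1
        strict = summarize_day(
            s.data, "s1", date(2021, 1, 1), count_steps_without_hr=False
        )
        assert strict.total_steps == 10

    def test_records_spanning_two_dates_is_error(self):
        s = make_series([("2021-01-01T23:59", 70, 0), ("2021-01-02T00:00", 70, 0)])
        with pytest.raises(ValueError, match="span"):
            summarize_day(s.data, "s1", date(2021, 1, 1))

    def test_daily_summaries_agree_with_summarize_day(self):
        rng = np.random.default_rng(11)
        s = random_series(rng, study_days=3)
        table = daily_summaries(s)
        for row in table.itertuples():
            day_data = s.data[s.data.index.normalize() == pd.Timestamp(row.date)]
            single = summarize_day(day_data, s.subject_id, row.date)
            assert row.wear_minutes == single.wear_minutes
            assert row.total_steps == single.total_steps
            if single.mean_hr is None:
                assert pd.isna(row.mean_hr)
            else:
                assert row.mean_hr == pytest.approx(single.mean_hr)
            for rule in DEFAULT_RULES:
                assert getattr(row, f"valid_{rule.name}") == single.validity[rule.name]


class TestValidDayRules:
    def test_weartime80_hour_equivalent(self):
        assert PRESET_RULES["weartime80"].min_wear_hours == pytest.approx(19.2)

    @pytest.mark.parametrize(
        "steps,wear,rule,expected",
        [
            (1000, 1.0, "stepcount1000", False),  # strict: exactly 1000 fails
            (1001, 1.0, "stepcount1000", True),
            (5000, 0.80, "weartime80", False),  # strict: exactly 80% fails
            (5000, 0.801, "weartime80", True),
            (0, 0.0, "none", True),
        ],
    )
    def test_strict_threshold_semantics(self, steps, wear, rule, expected):
        assert PRESET_RULES[rule].is_valid(steps, wear) is expected

    @given(
        min_steps=st.one_of(st.none(), st.integers(0, 20000)),
        min_wear=st.one_of(st.none(), st.floats(0, 1)),
        bump_steps=st.integers(0, 5000),
        bump_wear=st.floats(0, 0.5),
        days=st.lists(
            st.tuples(st.integers(0, 1440), st.integers(0, 30000)),
            min_size=1,
            max_size=40,
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_raising_thresholds_never_adds_valid_days(
        self, min_steps, min_wear, bump_steps, bump_wear, days
    ):
        loose = ValidDayRule("loose", min_steps, min_wear)
        strict = ValidDayRule(
            "strict",
            None if min_steps is None else min_steps + bump_steps,
            None if min_wear is None else min(min_wear + bump_wear, 1.0),
        )
        loose_valid = [loose.is_valid(s, w / 1440) for w, s in days]
        strict_valid = [strict.is_valid(s, w / 1440) for w, s in days]
        assert sum(strict_valid) <= sum(loose_valid)
        # nesting: every strictly-valid day is also loosely valid
        assert all(not sv or lv for sv, lv in zip(strict_valid, loose_valid))

    def test_preset_nesting_on_random_fixture(self):
        rng = np.random.default_rng(5)
        s = random_series(rng, study_days=5)
        table = daily_summaries(s)
        assert not (table["valid_weartime80"] & ~table["valid_none"]).any()
        assert not (table["valid_stepcount1000"] & ~table["valid_none"]).any()


class TestEstimates:
    def test_mean_over_valid_days(self):
        table = pd.DataFrame(
            {
                "subject_id": "s1",
                "date": [date(2021, 1, d) for d in (1, 2)],
                "wear_minutes": [1440, 1440],
                "wear_fraction": [1.0, 1.0],
                "total_steps": [8000, 10000],
                "mean_hr": [70.0, 72.0],
                "n_records": [1440, 1440],
            }
        )
        est = estimate_subject(table, PRESET_RULES["none"])
        assert est.avg_daily_steps == 9000
        assert est.avg_daily_hr == 71
        assert est.n_valid_days == 2

    def test_zero_valid_days_gives_absent_estimates(self):
        s = series_from_daily([100, 50])  # never above 80% wear
        est = estimate_subject(daily_summaries(s), PRESET_RULES["weartime80"])
        assert est.n_valid_days == 0
        assert est.avg_daily_steps is None and est.avg_daily_hr is None

    def test_filter_then_average_brute_force(self):
        # 3 days; the middle one fails weartime80
        s = series_from_daily([1300, 600, 1200], steps_per_worn_minute=2)
        table = daily_summaries(s)
        est = estimate_subject(table, PRESET_RULES["weartime80"])
        keep = [r for r in table.itertuples() if r.wear_fraction > 0.8]
        assert est.n_valid_days == len(keep) == 2
        assert est.avg_daily_steps == pytest.approx(
            np.mean([r.total_steps for r in keep])
        )

    def test_full_compliance_makes_rules_equivalent(self):
        s = series_from_daily([1440] * 5, steps_per_worn_minute=3)
        table = daily_summaries(s)
        ests = [estimate_subject(table, r) for r in DEFAULT_RULES]
        assert len({e.avg_daily_steps for e in ests}) == 1
        assert len({e.avg_daily_hr for e in ests}) == 1
        assert len({e.n_valid_days for e in ests}) == 1


class TestMonthlyWearTrend:
    def test_geometric_decay_gives_constant_relative_change(self):
        wear = [1000] * 30 + [900] * 30 + [810] * 30
        trend = monthly_wear_trend(series_from_daily(wear))
        assert trend["month"].tolist() == [1, 2, 3]
        assert np.isnan(trend["rel_change"].iloc[0])
        np.testing.assert_allclose(trend["rel_change"].iloc[1:], [-0.1, -0.1])

    def test_constant_wear_has_zero_change(self):
        trend = monthly_wear_trend(series_from_daily([600] * 90))
        np.testing.assert_allclose(trend["rel_change"].iloc[1:], 0.0)

    def test_short_series_yields_single_block_without_changes(self):
        trend = monthly_wear_trend(series_from_daily([500] * 20))
        assert len(trend) == 1
        assert np.isnan(trend["rel_change"].iloc[0])

    def test_simulated_decay_recovers_configured_rate(self):
        from weartime.synthetic import (
            SyntheticCohortConfig,
            WearModel,
            generate_subject,
        )

        cfg = SyntheticCohortConfig(
            study_days=90,
            wear=WearModel(target_hours=16, monthly_decay=0.19, day_concentration=50.0),
        )
        changes = []
        for seed in range(40):
            series, _ = generate_subject(cfg, f"s{seed}", "g", seed)
            trend = monthly_wear_trend(series)
            changes.extend(trend["rel_change"].iloc[1:].tolist())
        assert np.mean(changes) == pytest.approx(-0.19, abs=0.02)
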