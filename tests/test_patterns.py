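"""Daily features, guideline scoring, imputation, adherence."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actitraj.config import CadenceThresholds, WINDOW_DAYS
from actitraj.patterns import (adherence_summary, daily_features, features_table,
                               impute_missing_days, participant_summary,
                               trajectory_matrix, who_status)

from conftest import make_day


class TestDailyFeatures:
    def test_hand_computed_mixed_day(self):
        # 30 min at 110 steps/min (08:00-08:29) + 60 min at 50 (16:00-16:59)
        day = make_day({**{8 * 60 + i: 110 for i in range(30)},
                        **{16 * 60 + i: 50 for i in range(60)}})
        f = daily_features(day)
        assert f.steps_total == 30 * 110 + 60 * 50 == 6300
        assert f.mvpa_minutes == 30
        assert f.active_minutes == 90
        assert f.vigorous_minutes == 0
        assert f.mvpa_steps == 3300
        assert f.morning_fraction == pytest.approx(3300 / 6300)

    def test_thresholds_inclusive_at_boundary(self):
        day = make_day({7 * 60: 100, 20 * 60: 20, 12 * 60: 130, 13 * 60: 19})
        f = daily_features(day)
        assert f.mvpa_minutes == 2      # 100 and 130 both count
        assert f.vigorous_minutes == 1  # exactly 130 counts
        assert f.active_minutes == 3    # 19 is below rest threshold

    def test_rejects_non_full_day(self):
        with pytest.raises(ValueError, match="full day"):
            daily_features(make_day({6 * 60: 25}))

    def test_custom_thresholds_respected(self):
        day = make_day({8 * 60: 60, 20 * 60: 10})
        f = daily_features(day, CadenceThresholds(rest=5, mvpa=50, vigorous=60))
        assert f.active_minutes == 2 and f.mvpa_minutes == 1 and f.vigorous_minutes == 1

    @given(st.dictionaries(st.integers(0, 1439), st.integers(1, 250),
                           min_size=2, max_size=200))
    @settings(max_examples=60, deadline=None)
    def test_feature_ordering_invariants(self, sparse):
        lo, hi = min(sparse), max(sparse)
        if hi - lo < 480:
            sparse[min(lo, 900)] = 5
            sparse[min(lo, 900) + 480] = 5
        f = daily_features(make_day(sparse))
        assert f.vigorous_minutes <= f.mvpa_minutes <= f.active_minutes <= 1440
        assert 0.0 <= f.morning_fraction <= 1.0
        assert f.mvpa_steps <= f.steps_total


class TestParticipantSummary:
    def _features(self, rows):
        df = pd.DataFrame(rows)
        for c in ("steps_total", "morning_fraction", "active_minutes",
                  "mvpa_minutes", "vigorous_minutes", "mvpa_steps"):
            df[c] = df.get(c, 0)
        return df

    def test_constant_days_weekly_is_seven_times_daily(self):
        rows = [{"participant_id": "P1", "day": d, "weekday": (d - 1) % 7,
                 "mvpa_minutes": 16} for d in range(1, 11)]
        s = participant_summary(self._features(rows))
        assert s.loc[0, "mvpa_min_per_week"] == pytest.approx(112.0)

    def test_two_day_mean(self):
        rows = [{"participant_id": "P1", "day": 1, "weekday": 0, "mvpa_minutes": 10},
                {"participant_id": "P1", "day": 2, "weekday": 1, "mvpa_minutes": 20}]
        s = participant_summary(self._features(rows))
        assert s.loc[0, "mvpa_minutes"] == pytest.approx(15.0)
        assert s.loc[0, "mvpa_min_per_week"] == pytest.approx(105.0)

    def test_week_sum_mode_matches_daily_mean_on_complete_weeks(self):
        rows = [{"participant_id": "P1", "day": d, "weekday": (d - 1) % 7,
                 "mvpa_minutes": 10 + (d % 3)} for d in range(1, 15)]
        f = self._features(rows)
        a = participant_summary(f, weekly_mode="daily-mean")
        b = participant_summary(f, weekly_mode="week-sum")
        assert a.loc[0, "mvpa_min_per_week"] == pytest.approx(
            b.loc[0, "mvpa_min_per_week"])

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            participant_summary(self._features([]).iloc[0:0])


class TestWhoStatus:
    def _summary(self, **kw):
        base = {"participant_id": "P1", "steps_total": 5000.0,
                "mvpa_min_per_week": 0.0, "vigorous_min_per_week": 0.0}
        base.update(kw)
        return pd.Series(base)

    def test_weekly_mvpa_boundary_inclusive(self):
        assert who_status(self._summary(mvpa_min_per_week=150.0)).who_mvpa_met
        assert not who_status(self._summary(mvpa_min_per_week=149.9)).who_mvpa_met

    def test_vigorous_route_to_who(self):
        s = who_status(self._summary(vigorous_min_per_week=75.0))
        assert s.who_vigorous_met and s.who_met and not s.who_mvpa_met

    def test_step_thresholds_nested(self):
        s = who_status(self._summary(steps_total=9999.0))
        assert not s.steps10k_met and s.steps7k_met
        s2 = who_status(self._summary(steps_total=10_000.0))
        assert s2.steps10k_met and s2.steps7k_met

    def test_monotone_in_activity(self):
        lo = who_status(self._summary(mvpa_min_per_week=151, steps_total=10_500))
        hi = who_status(self._summary(mvpa_min_per_week=200, steps_total=12_000))
        for attr in ("who_mvpa_met", "steps10k_met", "steps7k_met"):
            assert getattr(hi, attr) >= getattr(lo, attr)


class TestImputation:
    def _matrix(self, values):
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(len(values))],
                          columns=range(1, len(values[0]) + 1))
        df.columns.name = "day"
        return df

    def test_missing_monday_gets_monday_mean(self):
        row = [np.nan if d == 1 else float(d % 7 + 10 * ((d - 1) % 7 == 0))
               for d in range(1, 91)]
        mat = self._matrix([row])
        imp = impute_missing_days(mat)
        mondays = [row[d - 1] for d in range(1, 91) if (d - 1) % 7 == 0 and d != 1]
        assert imp.iloc[0, 0] == pytest.approx(np.mean(mondays))

    def test_no_missing_is_identity(self):
        mat = self._matrix([[float(d) for d in range(1, 91)]])
        pd.testing.assert_frame_equal(impute_missing_days(mat), mat)

    def test_observed_cells_bit_identical_and_complete_output(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2.0, 8.0, (12, 90))
        vals[rng.random((12, 90)) < 0.2] = np.nan
        mat = self._matrix(vals.tolist())
        imp = impute_missing_days(mat)
        obs = ~np.isnan(vals)
        assert np.array_equal(imp.to_numpy()[obs], vals[obs])
        assert not imp.isna().any().any()

    def test_imputation_preserves_observed_weekday_means(self):
        rng = np.random.default_rng(4)
        vals = rng.gamma(2.0, 8.0, (20, 90))
        vals[rng.random((20, 90)) < 0.15] = np.nan
        vals[:, 0] = np.nan  # everyone misses day 1
        mat = self._matrix(vals.tolist())
        imp = impute_missing_days(mat)
        weekday = (np.arange(90)) % 7
        for wd in range(7):
            cols = np.flatnonzero(weekday == wd)
            pre = np.nanmean(vals[:, cols], axis=1)
            post = imp.to_numpy()[:, cols].mean(axis=1)
            ok = ~np.isnan(pre)
            np.testing.assert_allclose(post[ok], pre[ok], rtol=1e-12)

    def test_fully_missing_weekday_falls_back_to_overall_mean(self):
        vals = np.full((1, 90), 10.0)
        weekday = np.arange(90) % 7
        vals[0, weekday == 6] = np.nan  # no Sunday ever observed
        imp = impute_missing_days(self._matrix(vals.tolist()))
        assert imp.iloc[0, 6] == pytest.approx(10.0)

    def test_all_missing_participant_rejected(self):
        vals = [[np.nan] * 90, [1.0] * 90]
        with pytest.raises(ValueError, match="P0"):
            impute_missing_days(self._matrix(vals))


class TestCohortLevel:
    def test_features_table_invariants_on_synthetic(self, small_analyzable):
        f = features_table(small_analyzable)
        assert (f["mvpa_minutes"] <= f["active_minutes"]).all()
        assert (f["vigorous_minutes"] <= f["mvpa_minutes"]).all()
        assert (f["mvpa_steps"] <= f["steps_total"]).all()
        assert f["morning_fraction"].between(0, 1).all()

    def test_trajectory_matrix_marks_non_full_days_missing(self, small_analyzable):
        f = features_table(small_analyzable)
        mat = trajectory_matrix(f, "mvpa_minutes")
        p = small_analyzable[0]
        row = mat.loc[p.participant_id]
        assert row.notna().sum() == p.n_complete_days
        assert set(row.dropna().index) == set((np.flatnonzero(p.full_day) + 1))

    def test_adherence_counts_any_record_days(self, small_assembled):
        a = adherence_summary(small_assembled)
        assert 0 < a.mean_days_worn <= WINDOW_DAYS
        assert a.mean_pct_days_worn == pytest.approx(
            100 * a.mean_days_worn / WINDOW_DAYS)
        assert 0 <= a.fraction_ge_80_days <= 1
        assert 0 <= a.fraction_wearing_at_end <= 1
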