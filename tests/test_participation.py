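"""Bout extraction, daily roll-up, adherence and temporal patterns."""

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from conftest import make_series
from physiotrack.participation import (ExerciseBout, adherent_days_fraction,
                                       daily_rollup, extract_bouts,
                                       phase_comparison, temporal_patterns,
                                       weekly_minutes)
from physiotrack import CohortSimConfig, gen_cohort
from physiotrack.pipeline import ground_truth_daily


def _bout(pid="p0", day=4, hour=10, minute=0, dur_min=10.0, setting="home"):
    return ExerciseBout(pid, setting, datetime(2021, 1, day, hour, minute),
                        dur_min * 60)


class TestExtractBouts:
    def test_run_length_oracle(self):
        """Stream 1,1,1,0,0,1,1 with 10 s windows -> bouts of 30 s and 20 s."""
        series = make_series([1, 1, 1, 0, 0, 1, 1])
        bouts = extract_bouts(series, smoothing_width=1, min_bout_s=20)
        assert [b.duration_s for b in bouts] == [30.0, 20.0]
        assert bouts[0].start_datetime == datetime(2021, 1, 4, 10, 0)
        assert bouts[1].start_datetime == datetime(2021, 1, 4, 10, 0, 50)

    def test_min_bout_filter(self):
        series = make_series([1, 1, 1, 0, 0, 1, 1])
        bouts = extract_bouts(series, smoothing_width=1, min_bout_s=30)
        assert [b.duration_s for b in bouts] == [30.0]

    def test_median_filter_removes_isolated_positive(self):
        series = make_series([0, 0, 1, 0, 0, 0])
        assert extract_bouts(series, smoothing_width=3, min_bout_s=10) == []

    def test_median_filter_fills_isolated_negative(self):
        series = make_series([1, 1, 0, 1, 1])
        bouts = extract_bouts(series, smoothing_width=3, min_bout_s=10)
        assert [b.duration_s for b in bouts] == [50.0]

    def test_all_negative_stream(self):
        assert extract_bouts(make_series([0] * 10)) == []

    def test_even_smoothing_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            extract_bouts(make_series([1, 1]), smoothing_width=2)


class TestDailyRollup:
    @pytest.mark.parametrize("minutes,expected_ratio", [
        (20.0, 1.0), (10.0, 0.5), (45.0, 1.0)])
    def test_participation_ratio_capped(self, minutes, expected_ratio):
        daily = daily_rollup([_bout(dur_min=minutes)])
        assert daily.participation_ratio.iloc[0] == pytest.approx(expected_ratio)

    def test_minutes_split_by_setting(self):
        daily = daily_rollup([_bout(dur_min=8, setting="home"),
                              _bout(hour=14, dur_min=10, setting="clinic")])
        row = daily.iloc[0]
        assert row.minutes_home == pytest.approx(8.0)
        assert row.minutes_clinic == pytest.approx(10.0)
        assert row.participation_ratio == pytest.approx(18 / 20)

    def test_session_grouping_by_gap(self):
        # bouts at 10:00 (+10 min), 10:20, 12:00 -> gaps 10 min and 95 min
        bouts = [_bout(hour=10, minute=0, dur_min=10),
                 _bout(hour=10, minute=20, dur_min=10),
                 _bout(hour=12, minute=0, dur_min=10)]
        daily = daily_rollup(bouts, session_gap_min=30)
        assert daily.session_count.iloc[0] == 2

    def test_conservation_of_minutes(self, rng):
        """Sum of daily minutes equals sum of retained bout durations."""
        bouts = [_bout(day=int(rng.integers(4, 18)),
                       hour=int(rng.integers(6, 22)),
                       dur_min=float(rng.uniform(2, 20)))
                 for _ in range(40)]
        daily = daily_rollup(bouts)
        total = (daily.minutes_home + daily.minutes_clinic).sum()
        assert total == pytest.approx(sum(b.duration_s for b in bouts) / 60)


class TestAdherentDays:
    def test_enumeration_oracle_toy_calendar(self):
        """3-patient toy calendar checked against manual day counting."""
        days = [date(2021, 1, d) for d in range(4, 11)]     # 7 days each
        assigned = pd.DataFrame(
            [(p, d) for p in ("a", "b", "c") for d in days],
            columns=["patient_id", "date"])
        bouts = ([_bout("a", day=d, dur_min=10) for d in (4, 5, 6)]
                 + [_bout("b", day=7, dur_min=5)])          # c never
        daily = daily_rollup(bouts)
        frac = adherent_days_fraction(daily, assigned)
        assert frac == pytest.approx(4 / 21)

    def test_printed_counts_reproduce_cohort_rate(self):
        """1388 participating of 3386 assigned days -> 41%."""
        n_assigned, n_active = 3386, 1388
        assigned = pd.DataFrame({
            "patient_id": "p",
            "date": [date(2000, 1, 1) + timedelta(days=i)
                     for i in range(n_assigned)]})
        daily = daily_rollup([
            ExerciseBout("p", "home",
                         datetime(2000, 1, 1, 10) + timedelta(days=i), 600)
            for i in range(n_active)])
        frac = adherent_days_fraction(daily, assigned)
        assert round(100 * frac) == 41

    def test_no_participation(self):
        assigned = pd.DataFrame({"patient_id": ["a"], "date": [date(2021, 1, 4)]})
        assert adherent_days_fraction(daily_rollup([]), assigned) == 0.0

    def test_zero_assigned_days_rejected(self):
        with pytest.raises(ValueError):
            adherent_days_fraction(daily_rollup([]), pd.DataFrame(
                columns=["patient_id", "date"]))


class TestPhaseComparison:
    def _weekly(self, values_by_patient):
        rows = [(p, w + 1, m) for p, vals in values_by_patient.items()
                for w, m in enumerate(vals)]
        return pd.DataFrame(rows, columns=["patient_id", "week", "minutes"])

    def test_identical_phases_give_t0_p1(self):
        wk = self._weekly({"a": [30.0] * 12, "b": [10.0] * 12})
        res = phase_comparison(wk)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_sign_flip_antisymmetry(self):
        wk = self._weekly({p: list(np.linspace(40, 5, 12) + i)
                           for i, p in enumerate("abcd")})
        res = phase_comparison(wk)
        flipped = self._weekly({p: list(np.linspace(5, 40, 12) + i)
                                for i, p in enumerate("abcd")})
        res2 = phase_comparison(flipped)
        assert res.t_statistic == pytest.approx(-res2.t_statistic)
        assert res.p_value == pytest.approx(res2.p_value)

    def test_declining_cohort_detected(self):
        """Generator with decline < 1, 40 patients: late median < early
        median with a significant paired t."""
        cfg = CohortSimConfig(n_patients=40, seed=13)   # decline 0.91
        c = gen_cohort(cfg)
        daily = ground_truth_daily({"ground_truth_participation": c.ground_truth})
        starts = {p: cfg.start_date for p in c.baselines.patient_id}
        wk = weekly_minutes(daily, starts, cfg.weeks, "home")
        res = phase_comparison(wk)
        assert res.median_late < res.median_early
        assert res.t_statistic > 0 and res.p_value < 0.05

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            phase_comparison(self._weekly({"a": [5.0] * 12}))


class TestTemporalPatterns:
    def test_single_time_single_bin(self):
        bouts = [_bout(day=d, hour=10, minute=5) for d in range(4, 9)]
        weekday, hour = temporal_patterns(bouts)
        assert hour[10] == 5 and hour.sum() == 5

    def test_histogram_conserves_session_count(self):
        bouts = [_bout(day=4 + i % 7, hour=6 + i % 12) for i in range(30)]
        weekday, hour = temporal_patterns(bouts)
        assert weekday.sum() == hour.sum() == 30

    def test_bimodal_cohort_modes_at_10_and_21(self):
        """1000+ generated home sessions: histogram modes in the 10 AM and
        9 PM bins."""
        c = gen_cohort(CohortSimConfig(n_patients=50, seed=29))
        home = c.sessions.query("setting == 'home'")
        assert len(home) > 1000
        bouts = []
        for r in home.itertuples(index=False):
            h = int(r.start_hour)
            m = int((r.start_hour - h) * 60)
            bouts.append(ExerciseBout(r.patient_id, "home",
                                      datetime.combine(r.date,
                                                       datetime.min.time())
                                      + timedelta(hours=h, minutes=m),
                                      r.minutes * 60))
        _, hour = temporal_patterns(bouts, session_gap_min=1)
        assert hour.idxmax() == 21                            # evening mode
        assert hour.loc[5:15].idxmax() == 10                  # morning mode
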