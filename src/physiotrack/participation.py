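"""From window predictions to participation minutes, ratios and patterns.

A classifier's per-window exercise/ADL stream is smoothed and run-length
encoded into *bouts* (contiguous exercise intervals surviving a minimum
duration), bouts are grouped into *sessions* (gaps under 30 minutes) and
rolled up into per patient-day minutes. Daily participation is the ratio
of detected exercise minutes to a 20-minute daily expectation, capped at
100%. Descriptive statistics cover adherent-day fraction, weekly minutes
by setting with an early-vs-late phase test, and day-of-week /
time-of-day session patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .fcn import PredictionSeries

__all__ = [
    "ExerciseBout", "extract_bouts", "daily_rollup",
    "adherent_days_fraction", "weekly_minutes", "phase_comparison",
    "temporal_patterns", "PhaseComparison",
]


@dataclass(frozen=True)
class ExerciseBout:
    """A maximal contiguous interval of detected exercise activity."""

    patient_id: str
    setting: str
    start_datetime: datetime
    duration_s: float

    @property
    def end_datetime(self) -> datetime:
        return self.start_datetime + timedelta(seconds=self.duration_s)


def extract_bouts(
    series: PredictionSeries,
    smoothing_width: int = 3,
    min_bout_s: float = 60.0,
    positive_class: int = 1,
) -> list[ExerciseBout]:
    """Turn a window prediction stream into exercise bouts.

    The binary stream (predicted class == ``positive_class``) is median
    filtered with an odd ``smoothing_width`` (1 disables smoothing),
    maximal positive runs become bouts, and bouts shorter than
    ``min_bout_s`` are discarded. The series must be a non-overlapping
    tiling so each window contributes its full length once.
    """
    if smoothing_width % 2 == 0:
        raise ValueError("smoothing_width must be odd")
    n = len(series)
    if n == 0:
        return []
    stream = (np.asarray(series.predicted) == positive_class).astype(int)
    if smoothing_width > 1 and n >= smoothing_width:
        from scipy.ndimage import median_filter
        stream = median_filter(stream, size=smoothing_width, mode="nearest")
    bouts: list[ExerciseBout] = []
    i = 0
    while i < n:
        if stream[i]:
            j = i
            while j < n and stream[j]:
                j += 1
            dur = (j - i) * series.window_s
            if dur >= min_bout_s:
                bouts.append(ExerciseBout(
                    series.patient_id, series.setting,
                    series.start_datetimes[i], dur))
            i = j
        else:
            i += 1
    return bouts


def _group_sessions(bouts: list[ExerciseBout],
                    session_gap_min: float) -> list[list[ExerciseBout]]:
    """Group time-ordered bouts of one patient into sessions by gap."""
    if not bouts:
        return []
    bouts = sorted(bouts, key=lambda b: b.start_datetime)
    sessions = [[bouts[0]]]
    for b in bouts[1:]:
        gap = (b.start_datetime - sessions[-1][-1].end_datetime).total_seconds()
        if gap < session_gap_min * 60:
            sessions[-1].append(b)
        else:
            sessions.append([b])
    return sessions


def daily_rollup(
    bouts: list[ExerciseBout],
    expectation_min: float = 20.0,
    session_gap_min: float = 30.0,
) -> pd.DataFrame:
    """Aggregate bouts into per patient-day participation records.

    Returns columns ``patient_id, date, minutes_home, minutes_clinic,
    session_count, participation_ratio`` where the ratio is total
    detected minutes over the daily expectation, capped at 1. Bouts
    separated by less than ``session_gap_min`` form one session.
    """
    rows = []
    by_pd: dict[tuple[str, date], list[ExerciseBout]] = {}
    for b in bouts:
        by_pd.setdefault((b.patient_id, b.start_datetime.date()), []).append(b)
    for (pid, day), bs in sorted(by_pd.items()):
        mins_home = sum(b.duration_s for b in bs if b.setting == "home") / 60
        mins_clinic = sum(b.duration_s for b in bs if b.setting == "clinic") / 60
        n_sessions = len(_group_sessions(bs, session_gap_min))
        total = mins_home + mins_clinic
        rows.append((pid, day, mins_home, mins_clinic, n_sessions,
                     min(total / expectation_min, 1.0)))
    return pd.DataFrame(rows, columns=[
        "patient_id", "date", "minutes_home", "minutes_clinic",
        "session_count", "participation_ratio"])


def adherent_days_fraction(
    daily: pd.DataFrame,
    assigned_days: pd.DataFrame,
) -> float:
    """Fraction of assigned treatment days with >= 1 detected session.

    ``assigned_days`` enumerates each patient's treatment-period days
    (columns ``patient_id, date``); ``daily`` is the output of
    :func:`daily_rollup`. A day counts as participating when the daily
    record exists and has at least one session.
    """
    if len(assigned_days) == 0:
        raise ValueError("no assigned days")
    active = daily[daily.session_count >= 1][["patient_id", "date"]]
    merged = assigned_days[["patient_id", "date"]].merge(
        active.drop_duplicates(), on=["patient_id", "date"],
        how="left", indicator=True)
    return float((merged["_merge"] == "both").mean())


def weekly_minutes(
    daily: pd.DataFrame,
    treatment_start: dict[str, date],
    weeks: int,
    setting: str = "home",
) -> pd.DataFrame:
    """Per patient-week detected minutes in one setting, zero-filled.

    Weeks are indexed 1..``weeks`` from each patient's treatment start
    date (not calendar weeks); weeks without any detected exercise count
    zero minutes.
    """
    col = {"home": "minutes_home", "clinic": "minutes_clinic"}[setting]
    rows = []
    for pid, start in treatment_start.items():
        sub = daily[daily.patient_id == pid]
        week_min = np.zeros(weeks)
        for r in sub.itertuples(index=False):
            w = (r.date - start).days // 7
            if 0 <= w < weeks:
                week_min[w] += getattr(r, col)
        for w in range(weeks):
            rows.append((pid, w + 1, week_min[w]))
    return pd.DataFrame(rows, columns=["patient_id", "week", "minutes"])


@dataclass
class PhaseComparison:
    median_early: float
    median_late: float
    t_statistic: float
    p_value: float
    n: int


def phase_comparison(
    weekly: pd.DataFrame,
    early_weeks: tuple[int, int] = (1, 4),
    late_weeks: tuple[int, int] = (9, 12),
) -> PhaseComparison:
    """Early-vs-late change in weekly exercise minutes.

    Each patient contributes their mean weekly minutes over the early
    and late phase; the cohort medians are reported and a paired
    two-sided t-test is run on the patient-level phase means. All-zero
    differences return t = 0, p = 1 (no evidence of change).
    """
    e0, e1 = early_weeks
    l0, l1 = late_weeks
    early = (weekly[weekly.week.between(e0, e1)]
             .groupby("patient_id")["minutes"].mean())
    late = (weekly[weekly.week.between(l0, l1)]
            .groupby("patient_id")["minutes"].mean())
    both = early.index.intersection(late.index)
    if len(both) < 2:
        raise ValueError("need >= 2 patients present in both phases")
    e = early.loc[both].to_numpy()
    l = late.loc[both].to_numpy()
    diffs = e - l
    if np.allclose(diffs, 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(e, l)
    return PhaseComparison(float(np.median(e)), float(np.median(l)),
                           float(t), float(p), len(both))


def temporal_patterns(
    bouts: list[ExerciseBout],
    session_gap_min: float = 30.0,
) -> tuple[pd.Series, pd.Series]:
    """Day-of-week and time-of-day distributions of exercise sessions.

    Bouts are grouped into sessions per patient; each session is counted
    once at its first bout's local start time. Returns (weekday counts
    Mon..Sun, 24-bin histogram of start hours, midnight to midnight).
    Hour bin ``h`` collects sessions starting nearest to ``h:00``
    (i.e. within [h-0.5, h+0.5) hours, wrapping at midnight), so a peak
    labeled 10 means sessions cluster around 10 AM.
    """
    by_patient: dict[str, list[ExerciseBout]] = {}
    for b in bouts:
        by_patient.setdefault(b.patient_id, []).append(b)
    starts: list[datetime] = []
    for bs in by_patient.values():
        for sess in _group_sessions(bs, session_gap_min):
            starts.append(sess[0].start_datetime)
    weekday = pd.Series(0, index=range(7), name="sessions")
    hour = pd.Series(0, index=range(24), name="sessions")
    for s in starts:
        weekday[s.weekday()] += 1
        hour[int(round(s.hour + s.minute / 60.0)) % 24] += 1
    weekday.index = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
    return weekday, hour
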