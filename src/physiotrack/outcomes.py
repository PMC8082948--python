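"""Clinical outcome scoring and participation-recovery statistics.

Outcomes are the DASH disability score (0-100, higher = worse) and a
3-item numeric pain rating scale (NPRS, 0-10) assessed at baseline and
4/8/12 weeks. Improvement is baseline minus follow-up, so positive
change means recovery and a positive dose-response slope means more
exercise participation, more recovery. The dose-response is an ordinary
least-squares fit of improvement on cumulative participation percent;
the minimal clinically important difference (MCID) divided by that slope
gives the participation increase associated with a clinically meaningful
change. Univariable adherence predictors use Pearson (continuous),
Spearman (ordinal) or two-sample t (binary) tests, unadjusted, matching
an exploratory analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "nprs_score", "improvement", "proportions", "cumulative_participation",
    "dose_response", "mcid_threshold", "predictor_analysis",
    "DoseResponseFit", "PredictorResult", "DASH_MCID", "NPRS_MCID_RANGE",
]

DASH_MCID = 10.83
NPRS_MCID_RANGE = (1.0, 2.2)


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting only)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def nprs_score(rest: float, activity: float, average_past_week: float) -> float:
    """Composite pain score: arithmetic mean of the three survey items."""
    for v in (rest, activity, average_past_week):
        if not (0.0 <= v <= 10.0):
            raise ValueError(f"NPRS item {v} outside [0, 10]")
    return (rest + activity + average_past_week) / 3.0


def improvement(baseline: float, followup: float) -> float:
    """Change score, positive = better, for both NPRS and DASH.

    A missing follow-up (None or NaN) returns NaN; callers drop NaNs
    per-timepoint (complete-case analysis).
    """
    if baseline is None or (isinstance(baseline, float) and math.isnan(baseline)):
        raise ValueError("baseline score is required")
    if followup is None or (isinstance(followup, float) and math.isnan(followup)):
        return float("nan")
    return float(baseline) - float(followup)


def proportions(changes, mcid: float) -> tuple[int, int]:
    """Percent of patients improving at all and improving beyond the MCID.

    ``improved`` means change > 0; ``exceeding`` means change > mcid.
    Both are reported to the nearest integer percent.
    """
    c = np.asarray([v for v in changes if not math.isnan(v)], dtype=float)
    if len(c) == 0:
        raise ValueError("no change scores")
    return (_round_half_away(100.0 * np.mean(c > 0)),
            _round_half_away(100.0 * np.mean(c > mcid)))


def cumulative_participation(
    daily: pd.DataFrame,
    assigned_days: pd.DataFrame,
    up_to_week: int,
    treatment_start: dict[str, date],
    home_assigned_only: bool = True,
) -> pd.Series:
    """Cumulative participation percent per patient at a timepoint.

    100 x the mean daily capped participation ratio over the patient's
    assigned days from treatment start up to (exclusive) week
    ``up_to_week``; assigned days without detected exercise count as 0.
    By default the denominator is home-assigned days (days without an
    in-clinic visit), while detected minutes from any setting count in
    the numerator via the daily ratio.
    """
    if len(assigned_days) == 0:
        raise ValueError("no assigned days")
    ad = assigned_days.copy()
    if home_assigned_only and "home_assigned" in ad.columns:
        ad = ad[ad.home_assigned]
    out = {}
    for pid, start in treatment_start.items():
        end = start + timedelta(days=7 * up_to_week)
        days = ad[(ad.patient_id == pid) & (ad.date >= start)
                  & (ad.date < end)]
        if len(days) == 0:
            raise ValueError(f"no assigned days for patient {pid} "
                             f"before week {up_to_week}")
        d = days.merge(
            daily[["patient_id", "date", "participation_ratio"]],
            on=["patient_id", "date"], how="left")
        out[pid] = 100.0 * d["participation_ratio"].fillna(0.0).mean()
    return pd.Series(out, name=f"participation_pct_{up_to_week}wk")


@dataclass
class DoseResponseFit:
    """OLS fit of outcome improvement on cumulative participation percent."""

    timepoint_weeks: int
    n: int
    slope: float
    intercept: float
    pearson_r: float
    p_value: float


def dose_response(
    participation_pct,
    improvements,
    timepoint_weeks: int,
) -> DoseResponseFit:
    """Least-squares regression of improvement on participation percent.

    Pairs with a missing improvement are dropped (complete case); at
    least 3 complete pairs and nonzero participation variance are
    required. The Pearson correlation and its two-sided p-value come
    with the fit.
    """
    x = np.asarray(participation_pct, dtype=float)
    y = np.asarray(improvements, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in participation")
    res = stats.linregress(x, y)
    return DoseResponseFit(timepoint_weeks, len(x), float(res.slope),
                           float(res.intercept), float(res.rvalue),
                           float(res.pvalue))


def mcid_threshold(mcid: float, slope: float) -> int:
    """Participation-percent increase associated with an MCID-sized change.

    ``mcid / slope`` rounded to the nearest integer percent. A
    non-positive slope means no finite participation increase reaches
    the MCID, which is an error.
    """
    if mcid <= 0:
        raise ValueError("mcid must be positive")
    if slope <= 0:
        raise ValueError("threshold undefined for non-positive slope")
    return _round_half_away(mcid / slope)


# ---------------------------------------------------------------------------
# univariable adherence predictors
# ---------------------------------------------------------------------------

#: variable -> test type for the default synthetic baseline table
DEFAULT_PREDICTOR_TYPES = {
    "age": "continuous",
    "bmi": "continuous",
    "nprs_baseline": "continuous",
    "baseline_activity_hr_wk": "continuous",
    "essi": "ordinal",
    "pseq": "ordinal",
    "peq": "ordinal",
    "hads_anxiety": "ordinal",
    "hads_depression": "ordinal",
    "income": "ordinal",
    "sex_male": "binary",
    "working": "binary",
    "compensation_claim": "binary",
    "education_university": "binary",
}


@dataclass
class PredictorResult:
    variable: str
    test: str                      # pearson | spearman | two-sample-t
    statistic: float               # r, rho, or t
    p_value: float
    group_means: tuple | None = None   # (mean1, sd1, mean0, sd0) for binary


def predictor_analysis(
    baselines: pd.DataFrame,
    participation_pct: pd.Series,
    variable_types: dict[str, str] | None = None,
) -> list[PredictorResult]:
    """Univariable tests of baseline variables against participation.

    Continuous variables use Pearson correlation, ordinal variables
    Spearman rank correlation, and binary variables a two-sample t-test
    with per-group mean (SD) participation reported. P-values are
    two-sided and unadjusted for multiplicity (exploratory analysis).
    """
    variable_types = variable_types or DEFAULT_PREDICTOR_TYPES
    df = baselines.set_index("patient_id")
    part = participation_pct.reindex(df.index)
    results = []
    for var, kind in variable_types.items():
        if var not in df.columns:
            continue
        v = df[var].astype(float)
        keep = ~(v.isna() | part.isna())
        v, p = v[keep].to_numpy(), part[keep].to_numpy()
        if kind == "continuous":
            r, pval = stats.pearsonr(v, p)
            results.append(PredictorResult(var, "pearson", float(r), float(pval)))
        elif kind == "ordinal":
            rho, pval = stats.spearmanr(v, p)
            results.append(PredictorResult(var, "spearman", float(rho), float(pval)))
        elif kind == "binary":
            g1, g0 = p[v == 1], p[v == 0]
            if len(g1) == 0 or len(g0) == 0:
                raise ValueError(f"binary variable {var} has an empty group")
            t, pval = stats.ttest_ind(g1, g0)
            results.append(PredictorResult(
                var, "two-sample-t", float(t), float(pval),
                (float(g1.mean()), float(g1.std(ddof=1)) if len(g1) > 1 else 0.0,
                 float(g0.mean()), float(g0.std(ddof=1)) if len(g0) > 1 else 0.0)))
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var}")
    return results
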