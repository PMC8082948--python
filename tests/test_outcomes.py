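"""Outcome scoring, dose-response regression, MCID thresholds, predictors."""

import math
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from physiotrack import CohortSimConfig, gen_cohort
from physiotrack.outcomes import (cumulative_participation, dose_response,
                                  improvement, mcid_threshold, nprs_score,
                                  predictor_analysis, proportions)


class TestNprsScore:
    @pytest.mark.parametrize("items,expected", [
        ((6, 6, 6), 6.0), ((4, 6, 5), 5.0), ((0, 0, 0), 0.0)])
    def test_mean_of_items(self, items, expected):
        assert nprs_score(*items) == pytest.approx(expected)

    @pytest.mark.parametrize("items", [(11, 5, 5), (-1, 5, 5), (5, 5, 10.5)])
    def test_out_of_range_rejected(self, items):
        with pytest.raises(ValueError):
            nprs_score(*items)


class TestImprovement:
    def test_cohort_mean_examples(self):
        """Baseline-to-12-week changes: disability 44->35 gives 9 points,
        pain 5.2->3.4 gives 1.8 points."""
        assert improvement(44, 35) == pytest.approx(9.0)
        assert improvement(5.2, 3.4) == pytest.approx(1.8)
        assert improvement(7, 7) == 0.0

    def test_missing_followup_flagged(self):
        assert math.isnan(improvement(44, float("nan")))
        assert math.isnan(improvement(44, None))
        with pytest.raises(ValueError):
            improvement(float("nan"), 30)


class TestProportions:
    def test_cohort_fractions(self):
        """39/42 improved -> 93%; 20/42 beyond the disability MCID -> 48%."""
        changes = [1.0] * 39 + [-1.0] * 3
        assert proportions(changes, 10.83)[0] == 93
        changes = [12.0] * 20 + [5.0] * 14 + [-1.0] * 8
        improved, beyond = proportions(changes, 10.83)
        assert improved == 81 and beyond == 48

    def test_none_improved(self):
        assert proportions([-1.0, 0.0, -2.0], 1.0) == (0, 0)


class TestCumulativeParticipation:
    def _tables(self, ratios_by_day):
        start = date(2021, 1, 4)
        assigned = pd.DataFrame({
            "patient_id": "a",
            "date": [start + timedelta(days=i)
                     for i in range(len(ratios_by_day))],
            "home_assigned": True})
        daily = pd.DataFrame({
            "patient_id": "a",
            "date": [start + timedelta(days=i)
                     for i, r in enumerate(ratios_by_day) if r > 0],
            "participation_ratio": [r for r in ratios_by_day if r > 0]})
        return daily, assigned, {"a": start}

    def test_every_day_at_expectation(self):
        daily, assigned, starts = self._tables([1.0] * 7)
        part = cumulative_participation(daily, assigned, 1, starts)
        assert part["a"] == pytest.approx(100.0)

    def test_half_days_at_expectation(self):
        daily, assigned, starts = self._tables([1.0, 0, 1.0, 0, 1.0, 0, 1.0, 0,
                                                1.0, 0, 1.0, 0, 1.0, 0])
        part = cumulative_participation(daily, assigned, 2, starts)
        assert part["a"] == pytest.approx(50.0)

    def test_enumeration_oracle(self, rng):
        ratios = list(rng.uniform(0, 1, 21))
        daily, assigned, starts = self._tables(ratios)
        part = cumulative_participation(daily, assigned, 3, starts)
        assert part["a"] == pytest.approx(100 * np.mean(ratios))

    def test_no_assigned_days_rejected(self):
        daily, assigned, starts = self._tables([1.0])
        with pytest.raises(ValueError):
            cumulative_participation(daily, assigned.iloc[:0], 1, starts)


class TestDoseResponse:
    def test_exact_fit_recovers_planted_slope(self):
        x = np.array([10.0, 25.0, 40.0, 55.0, 70.0])
        y = 0.37 * x + 2.0
        fit = dose_response(x, y, 12)
        assert fit.slope == pytest.approx(0.37)
        assert fit.pearson_r == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_closed_form_oracle(self, seed):
        """Slope = cov/var, intercept = ybar - b*xbar, r = standard formula."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        x = rng.normal(50, 15, n)
        y = rng.normal(10, 5, n)
        fit = dose_response(x, y, 8)
        b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean())**2)
        r = (np.sum((x - x.mean()) * (y - y.mean()))
             / np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2)))
        assert fit.slope == pytest.approx(b)
        assert fit.intercept == pytest.approx(y.mean() - b * x.mean())
        assert fit.pearson_r == pytest.approx(r)
        assert fit.n == n

    def test_null_simulation_uniform_p(self):
        """Independent x, y: r stays small and p-values look uniform."""
        rng = np.random.default_rng(0)
        rs, ps = [], []
        for _ in range(200):
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            fit = dose_response(x, y, 4)
            rs.append(abs(fit.pearson_r))
            ps.append(fit.p_value)
        assert np.mean(rs) < 0.1
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            dose_response([1, 2], [1, 2], 4)
        with pytest.raises(ValueError):
            dose_response([5, 5, 5, 5], [1, 2, 3, 4], 4)

    def test_missing_pairs_dropped(self):
        x = [10, 20, 30, 40, np.nan]
        y = [1, 2, np.nan, 4, 5]
        assert dose_response(x, y, 4).n == 3


class TestMcidThreshold:
    @pytest.mark.parametrize("mcid,slope,expected", [
        (10.83, 0.37, 29),   # disability MCID over disability slope
        (1.0, 0.056, 18),    # lower pain MCID over pain slope
        (2.2, 0.056, 39),    # upper pain MCID over pain slope
    ])
    def test_reported_thresholds(self, mcid, slope, expected):
        assert mcid_threshold(mcid, slope) == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(mcid=st.floats(0.5, 30), slope=st.floats(0.01, 2),
           factor=st.floats(1.05, 3))
    def test_monotone_in_mcid_antitone_in_slope(self, mcid, slope, factor):
        base = mcid_threshold(mcid, slope)
        assert mcid_threshold(mcid * factor, slope) >= base
        assert mcid_threshold(mcid, slope * factor) <= base

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            mcid_threshold(10.83, 0.0)
        with pytest.raises(ValueError):
            mcid_threshold(10.83, -0.5)


class TestPredictorAnalysis:
    def _toy(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        part = pd.Series(rng.uniform(0, 80, n),
                         index=[f"P{i}" for i in range(n)])
        base = pd.DataFrame({
            "patient_id": part.index,
            "age": rng.normal(45, 13, n),
            "peq": part.rank().to_numpy(),          # perfectly monotone
            "sex_male": rng.integers(0, 2, n),
        })
        return base, part

    def test_monotone_ordinal_gives_rho_1(self):
        base, part = self._toy()
        res = {r.variable: r for r in predictor_analysis(
            base, part, {"peq": "ordinal"})}
        assert res["peq"].statistic == pytest.approx(1.0)

    def test_identical_group_distributions_give_t_zero(self):
        base = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(40)],
            "flag": [0, 1] * 20})
        # both groups see the exact same participation values (10, 30, ...)
        part = pd.Series(np.tile([10.0, 10.0, 30.0, 30.0], 10),
                         index=base.patient_id)
        res = predictor_analysis(base, part, {"flag": "binary"})[0]
        assert abs(res.statistic) < 1e-9
        assert res.p_value == pytest.approx(1.0)

    def test_test_selection_by_type(self):
        base, part = self._toy()
        res = {r.variable: r for r in predictor_analysis(
            base, part, {"age": "continuous", "peq": "ordinal",
                         "sex_male": "binary"})}
        assert res["age"].test == "pearson"
        assert res["peq"].test == "spearman"
        assert res["sex_male"].test == "two-sample-t"
        assert res["sex_male"].group_means is not None

    def test_empty_group_rejected(self):
        base, part = self._toy()
        base["sex_male"] = 1
        with pytest.raises(ValueError):
            predictor_analysis(base, part, {"sex_male": "binary"})

    def test_planted_expectation_effect_detected(self):
        """200-patient cohort: the planted positive expectation effect is
        significant; null covariates stay at the nominal false-positive
        rate."""
        cfg = CohortSimConfig(n_patients=200, seed=31)
        c = gen_cohort(cfg)
        part4 = (c.true_participation.query("week == 4")
                 .set_index("patient_id").participation_pct)
        res = {r.variable: r for r in predictor_analysis(c.baselines, part4)}
        assert res["peq"].statistic > 0 and res["peq"].p_value < 0.01
        assert res["hads_anxiety"].statistic < 0
        assert res["hads_anxiety"].p_value < 0.05
        # covariates with no planted effect should not be strongly significant
        null_ps = [res[v].p_value for v in ("bmi", "sex_male", "working")]
        assert min(null_ps) > 1e-3
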