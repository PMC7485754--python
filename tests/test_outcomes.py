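"""Annual aggregation identities and the adjusted outcome models."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from trdclaims.outcomes import (
    annualize_outcomes,
    bootstrap_difference,
    fit_cost_model,
    fit_count_model,
    fit_repeated_logistic,
    pivot_outcomes,
    subgroup_costs_by_diagnosis,
)

from .conftest import INDEX_DATE, med, med_frame, rx, rx_frame


def _cohort(pids=("P1",)):
    return pd.DataFrame({"patient_id": list(pids), "index_date": [INDEX_DATE] * len(pids)})


class TestAnnualize:
    def test_no_claims_yields_zero_rows_for_all_years(self):
        out = annualize_outcomes(_cohort(), med_frame([]), rx_frame([]))
        assert len(out) == 3
        assert (out[["outpatient_visits", "hospital_los", "total_healthcare"]] == 0).all().all()
        assert not out["any_ed"].any() and not out["any_hospitalization"].any()

    def test_single_inpatient_stay_assigned_to_year_one(self):
        claims = med_frame([med(offset=100, end_offset=104, setting="inpatient")])
        out = annualize_outcomes(_cohort(), claims, rx_frame([])).set_index("follow_year")
        assert out.loc[1, "hospital_los"] == 5
        assert bool(out.loc[1, "any_hospitalization"])
        assert out.loc[2, "hospital_los"] == 0
        assert out.loc[1, "outpatient_visits"] == 0

    def test_identity_inflation_reproduces_raw_sums(self):
        claims = med_frame([med(offset=10, payer=150.0, patient=30.0),
                            med(offset=400, payer=200.0, patient=0.0)])
        fills = rx_frame([rx(offset=5, payer=40.0, patient=10.0)])
        out = annualize_outcomes(_cohort(), claims, fills).set_index("follow_year")
        assert out.loc[1, "payer_medical"] == 150.0
        assert out.loc[1, "payer_pharmacy"] == 40.0
        assert out.loc[1, "patient_total"] == 40.0
        assert out.loc[1, "total_healthcare"] == 230.0
        assert out.loc[2, "total_healthcare"] == 200.0

    def test_inflation_factor_applied_by_calendar_year(self):
        claims = med_frame([med(offset=10, payer=100.0, patient=0.0)])  # 2013 claim
        out = annualize_outcomes(_cohort(), claims, rx_frame([]), {2013: 1.10})
        assert out.set_index("follow_year").loc[1, "payer_medical"] == pytest.approx(110.0)

    def test_accounting_identities_hold_on_generated_bundle(self, small_bundle):
        cohort = small_bundle.ground_truth.rename(columns={"index_date": "index_date"})
        out = annualize_outcomes(cohort[["patient_id", "index_date"]],
                                 small_bundle.medical_claims, small_bundle.pharmacy_claims)
        np.testing.assert_allclose(out["payer_total"],
                                   out["payer_medical"] + out["payer_pharmacy"])
        np.testing.assert_allclose(out["patient_total"],
                                   out["patient_medical"] + out["patient_rx"])
        np.testing.assert_allclose(out["total_healthcare"],
                                   out["payer_total"] + out["patient_total"])
        assert (out[["outpatient_visits", "hospital_los"]] >= 0).all().all()
        wide = pivot_outcomes(out)
        assert len(wide) == len(cohort)


class TestCountModel:
    def test_poisson_limit_agrees_with_poisson_glm(self):
        rng = np.random.default_rng(5)
        n = 4000
        trd = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        base = rng.poisson(8, n)
        y = rng.poisson(np.exp(np.log(8) + 0.3 * trd))
        res = fit_count_model(y, trd, base)
        X = pd.DataFrame({"const": 1.0, "trd": trd, "baseline": base.astype(float)})
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        X1, X0 = X.copy(), X.copy()
        X1["trd"], X0["trd"] = 1.0, 0.0
        expected = float(pois.predict(X1).mean() - pois.predict(X0).mean())
        assert res.difference == pytest.approx(expected, rel=0.02)
        assert res.extra["nb_dispersion"] < 0.05

    def test_recovers_injected_mean_ratio(self):
        rng = np.random.default_rng(6)
        n = 5000
        trd = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        mean = 8.0 * np.where(trd == 1, 1.5, 1.0)
        r = 1 / 0.8
        y = rng.negative_binomial(r, r / (r + mean))
        base = rng.negative_binomial(r, r / (r + 8.0), n)
        res = fit_count_model(y, trd, base)
        assert res.ratio == pytest.approx(1.5, rel=0.10)

    def test_all_zero_outcome_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_count_model(np.zeros(10), np.r_[np.ones(5), np.zeros(5)], np.zeros(10))


class TestCostModel:
    def test_linear_family_matches_hand_least_squares(self):
        # 6-row fixture solved with the normal equations as the oracle
        y = np.array([100.0, 160.0, 220.0, 80.0, 140.0, 200.0])
        trd = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        base = np.array([10.0, 20.0, 30.0, 10.0, 20.0, 30.0])
        X = np.column_stack([np.ones(6), trd, base])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        res = fit_cost_model(y, trd, base, family="linear_normal")
        assert res.difference == pytest.approx(beta[1], abs=1e-8)

    def test_gamma_recovers_multiplicative_effect(self):
        rng = np.random.default_rng(7)
        n = 5000
        trd = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        mean = 8000.0 * np.where(trd == 1, 1.4, 1.0)
        y = rng.gamma(1.5, mean / 1.5)
        base = rng.gamma(1.5, 8000 / 1.5, n)
        res = fit_cost_model(y, trd, base)
        assert res.ratio == pytest.approx(1.4, rel=0.10)

    def test_exact_zeros_shifted_and_counted(self):
        y = np.array([0.0, 50.0, 100.0, 0.0, 60.0, 90.0])
        trd = np.array([1, 1, 1, 0, 0, 0.0])
        res = fit_cost_model(y, trd, np.ones(6))
        assert res.extra["zero_costs_shifted"] == 2

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fit_cost_model(np.array([-1.0, 2.0]), np.array([1.0, 0.0]), np.ones(2))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            fit_cost_model(np.ones(4), np.array([1, 1, 0, 0.0]), np.ones(4), family="tweedie")


class TestBootstrap:
    DATA = pd.DataFrame({"trd": np.r_[np.ones(60), np.zeros(60)],
                         "x": np.random.default_rng(8).normal(10, 2, 120)})

    def test_constant_estimator_gives_zero_width_interval(self):
        lo, hi, fails = bootstrap_difference(lambda df: 3.25, self.DATA, 200, seed=1)
        assert lo == hi == 3.25 and fails == 0

    def test_same_seed_reproduces_and_seeds_differ(self):
        est = lambda df: df.loc[df["trd"] == 1, "x"].mean() - df.loc[df["trd"] == 0, "x"].mean()
        a = bootstrap_difference(est, self.DATA, 200, seed=11)
        b = bootstrap_difference(est, self.DATA, 200, seed=11)
        c = bootstrap_difference(est, self.DATA, 200, seed=12)
        assert a == b and a != c

    def test_percentile_interval_near_t_interval_for_normal_mean(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"trd": np.zeros(200), "x": rng.normal(5, 1, 200)})
        df.loc[:0, "trd"] = 1  # one-patient arm so strata resampling is exercised
        est = lambda d: d["x"].mean()
        lo, hi, _ = bootstrap_difference(est, df, 1000, seed=2)
        t_lo, t_hi = stats.t.interval(0.95, len(df) - 1, loc=df["x"].mean(),
                                      scale=stats.sem(df["x"]))
        width = t_hi - t_lo
        assert abs(lo - t_lo) < 0.10 * width and abs(hi - t_hi) < 0.10 * width

    def test_persistent_estimator_failure_aborts(self):
        def bad(df):
            raise RuntimeError("no fit")
        with pytest.raises(RuntimeError, match="bootstrap"):
            bootstrap_difference(bad, self.DATA, 50, seed=3)


def _or_data(rng, n=4000, or1=1.0, or2=1.0):
    from scipy.special import expit, logit
    trd = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    rows = []
    for year, orr in ((1, or1), (2, or2)):
        p = expit(logit(0.2) + np.log(orr) * trd)
        rows.append(pd.DataFrame({
            "patient_id": np.arange(n), "year": year,
            "y": (rng.random(n) < p).astype(int), "trd": trd,
            "baseline": rng.integers(0, 2, n), "elixhauser": rng.poisson(1.5, n)}))
    return pd.concat(rows, ignore_index=True)


class TestRepeatedLogistic:
    def test_independence_structure_matches_plain_logistic(self):
        rng = np.random.default_rng(10)
        long = _or_data(rng, n=3000, or1=1.6, or2=1.3)
        gee = fit_repeated_logistic(long, "any_ed", cov_struct="independence")
        X = pd.DataFrame({"const": 1.0, "trd": long["trd"],
                          "year2": (long["year"] == 2).astype(float),
                          "baseline": long["baseline"].astype(float),
                          "elixhauser": long["elixhauser"].astype(float)})
        X["trd_x_year2"] = X["trd"] * X["year2"]
        logit_fit = sm.Logit(long["y"], X).fit(disp=0)
        assert gee[0].odds_ratio == pytest.approx(np.exp(logit_fit.params["trd"]), rel=1e-4)

    def test_recovers_per_year_odds_ratios(self):
        rng = np.random.default_rng(11)
        results = fit_repeated_logistic(_or_data(rng, n=6000, or1=1.7, or2=1.4), "any_ed")
        assert results[0].odds_ratio == pytest.approx(1.7, rel=0.15)
        assert results[1].odds_ratio == pytest.approx(1.4, rel=0.15)
        for r in results:
            assert r.ci_low < r.odds_ratio < r.ci_high

    def test_constant_outcome_in_a_year_rejected(self):
        rng = np.random.default_rng(12)
        long = _or_data(rng, n=200)
        long.loc[long["year"] == 2, "y"] = 0
        with pytest.raises(ValueError, match="constant"):
            fit_repeated_logistic(long, "any_ed")


class TestSubgroups:
    def _wide(self, cats, trd):
        n = len(cats)
        rng = np.random.default_rng(13)
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "diagnosis_category": cats, "trd": trd,
            "y1_total_healthcare": rng.gamma(2, 4000, n),
            "base_total_healthcare": rng.gamma(2, 4000, n)})

    def test_single_category_yields_one_result(self):
        wide = self._wide(["296.X"] * 40, [1, 0] * 20)
        results, skips = subgroup_costs_by_diagnosis(wide)
        assert list(results) == ["296.X"] and skips == []

    def test_sparse_subgroup_skipped_with_reason(self):
        cats = ["296.X"] * 40 + ["311.X"] * 3
        trd = [1, 0] * 20 + [1, 0, 0]
        results, skips = subgroup_costs_by_diagnosis(self._wide(cats, trd))
        assert "311.X" in [s["category"] for s in skips]
        assert "too few" in skips[0]["reason"]
        assert list(results) == ["296.X"]
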