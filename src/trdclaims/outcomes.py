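"""Follow-up outcome aggregation and adjusted TRD vs non-TRD models.

Utilization and costs are aggregated per patient-year (year 1 = days 1–365
after index, year 2 = days 366–730; the pre-index 365 days form the
baseline year used as the model adjustment). Adjusted comparisons follow
the study design:

* counts (outpatient visits, hospital days) — log-link negative-binomial
  GLM on the TRD indicator adjusted for the baseline value; the dispersion
  is estimated by the Cameron–Trivedi auxiliary OLS regression on Poisson
  residuals and plugged into the NB family;
* costs — log-link gamma GLM (linear-normal family as sensitivity);
* binary use (any ED visit / any hospitalization) — repeated-measures
  logistic model over both follow-up years fitted by GEE with an
  exchangeable working correlation and robust variance, giving per-year
  odds ratios from the TRD main effect and the TRD×year interaction.

Adjusted group means come from recycled predictions: predict for the whole
sample with the TRD indicator toggled, then average. Confidence intervals
for adjusted differences use the percentile bootstrap with patients
resampled within arm (both follow-up years of a patient move together).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


OUTCOME_COLUMNS = [
    "outpatient_visits", "any_ed", "any_hospitalization", "hospital_los",
    "payer_medical", "payer_pharmacy", "payer_total",
    "patient_medical", "patient_rx", "patient_total", "total_healthcare",
]


@dataclass
class ModelResult:
    """Fitted adjusted comparison for one outcome and follow-up year."""

    outcome: str
    year: int
    family: str
    mean_trd: float
    mean_control: float
    difference: float
    ratio: float | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_trd: int = 0
    n_control: int = 0
    bootstrap_iterations: int = 0
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "outcome", "year", "family", "mean_trd", "mean_control", "difference",
            "ratio", "odds_ratio", "ci_low", "ci_high", "n_trd", "n_control",
            "bootstrap_iterations", "seed")}
        d.update(self.extra)
        return d


def _year_of_offset(offset_days: np.ndarray) -> np.ndarray:
    """Follow-year index: 0 = baseline, 1, 2 = follow-up; -1 = outside."""
    year = np.full(offset_days.shape, -1, dtype=int)
    year[(offset_days >= -365) & (offset_days <= -1)] = 0
    year[(offset_days >= 1) & (offset_days <= 365)] = 1
    year[(offset_days >= 366) & (offset_days <= 730)] = 2
    return year


def annualize_outcomes(cohort: pd.DataFrame, medical_claims: pd.DataFrame,
                       pharmacy_claims: pd.DataFrame,
                       inflation_table: dict | None = None) -> pd.DataFrame:
    """Per patient-year utilization/cost aggregates (years 0, 1, 2).

    Claims are assigned to years by service start (dispense date for
    pharmacy); inpatient length of stay is summed per year; costs are
    multiplied by the inflation factor of the claim's calendar year
    (identity when no table is given). Every cohort patient contributes all
    three year rows, zero-filled where no claims occurred; decedents keep
    whatever outcomes they accrued.
    """
    inflation_table = inflation_table or {}
    idx = cohort[["patient_id", "index_date"]].copy()
    idx["index_date"] = pd.to_datetime(idx["index_date"])

    med = medical_claims.merge(idx, on="patient_id", how="inner")
    med["service_start"] = pd.to_datetime(med["service_start"])
    med["service_end"] = pd.to_datetime(med["service_end"])
    med["follow_year"] = _year_of_offset(
        (med["service_start"] - med["index_date"]).dt.days.to_numpy())
    med = med[med["follow_year"] >= 0].copy()
    infl = med["service_start"].dt.year.map(lambda y: inflation_table.get(int(y), 1.0))
    med["payer_cost_adj"] = med["payer_cost"] * infl
    med["patient_cost_adj"] = med["patient_cost"] * infl
    med["los"] = np.where(
        med["setting"] == "inpatient",
        (med["service_end"] - med["service_start"]).dt.days + 1, 0)

    med["is_outpatient"] = (med["setting"] == "outpatient").astype(int)
    med["is_ed"] = (med["setting"] == "ed").astype(int)
    med["is_inpatient"] = (med["setting"] == "inpatient").astype(int)
    med_agg = med.groupby(["patient_id", "follow_year"]).agg(
        outpatient_visits=("is_outpatient", "sum"),
        any_ed=("is_ed", "max"),
        any_hospitalization=("is_inpatient", "max"),
        hospital_los=("los", "sum"),
        payer_medical=("payer_cost_adj", "sum"),
        patient_medical=("patient_cost_adj", "sum"),
    )

    rx = pharmacy_claims.merge(idx, on="patient_id", how="inner")
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    rx["follow_year"] = _year_of_offset(
        (rx["dispense_date"] - rx["index_date"]).dt.days.to_numpy())
    rx = rx[rx["follow_year"] >= 0].copy()
    infl = rx["dispense_date"].dt.year.map(lambda y: inflation_table.get(int(y), 1.0))
    rx["payer_cost_adj"] = rx["payer_cost"] * infl
    rx["patient_cost_adj"] = rx["patient_cost"] * infl
    rx_agg = rx.groupby(["patient_id", "follow_year"]).agg(
        payer_pharmacy=("payer_cost_adj", "sum"),
        patient_rx=("patient_cost_adj", "sum"))

    frame = pd.MultiIndex.from_product(
        [cohort["patient_id"], (0, 1, 2)], names=["patient_id", "follow_year"])
    out = pd.DataFrame(index=frame).join(med_agg).join(rx_agg).reset_index()
    for col in ("outpatient_visits", "any_ed", "any_hospitalization", "hospital_los",
                "payer_medical", "patient_medical", "payer_pharmacy", "patient_rx"):
        out[col] = pd.to_numeric(out[col], errors="coerce").fillna(0)
    out["outpatient_visits"] = out["outpatient_visits"].astype(int)
    out["hospital_los"] = out["hospital_los"].astype(int)
    out["any_ed"] = out["any_ed"].astype(bool)
    out["any_hospitalization"] = out["any_hospitalization"].astype(bool)
    out["payer_total"] = out["payer_medical"] + out["payer_pharmacy"]
    out["patient_total"] = out["patient_medical"] + out["patient_rx"]
    out["total_healthcare"] = out["payer_total"] + out["patient_total"]
    return out[["patient_id", "follow_year"] + OUTCOME_COLUMNS]


def pivot_outcomes(annual: pd.DataFrame) -> pd.DataFrame:
    """Wide per-patient table: ``base_<x>``, ``y1_<x>``, ``y2_<x>`` columns."""
    wide = annual.pivot(index="patient_id", columns="follow_year", values=OUTCOME_COLUMNS)
    prefix = {0: "base", 1: "y1", 2: "y2"}
    wide.columns = [f"{prefix[yr]}_{col}" for col, yr in wide.columns]
    return wide.reset_index()


def _recycled_means(result, X: pd.DataFrame, trd_col: str = "trd"):
    X1, X0 = X.copy(), X.copy()
    X1[trd_col], X0[trd_col] = 1.0, 0.0
    m1 = float(np.mean(result.predict(X1)))
    m0 = float(np.mean(result.predict(X0)))
    return m1, m0


def _model_frame(trd, baseline) -> pd.DataFrame:
    return pd.DataFrame({
        "const": 1.0,
        "trd": np.asarray(trd, dtype=float),
        "baseline": np.asarray(baseline, dtype=float),
    })


def estimate_nb_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Cameron–Trivedi auxiliary regression estimate of the NB2 dispersion."""
    z = ((y - mu) ** 2 - y) / mu
    alpha = float(np.sum(z * mu) / np.sum(mu ** 2))
    return max(alpha, 0.0)


def fit_count_model(y, trd, baseline, outcome: str = "count", year: int = 1) -> ModelResult:
    """Adjusted negative-binomial comparison of an annual count outcome."""
    y = np.asarray(y, dtype=float)
    trd = np.asarray(trd, dtype=float)
    if y.sum() == 0:
        raise ValueError(f"outcome '{outcome}' is zero for every patient in both arms")
    X = _model_frame(trd, baseline)
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    alpha = estimate_nb_dispersion(y, np.asarray(pois.fittedvalues))
    if alpha > 1e-8:
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    else:
        fit = pois
    m1, m0 = _recycled_means(fit, X)
    return ModelResult(
        outcome=outcome, year=year, family="negative_binomial",
        mean_trd=m1, mean_control=m0, difference=m1 - m0, ratio=m1 / m0,
        n_trd=int(trd.sum()), n_control=int((1 - trd).sum()),
        extra={"nb_dispersion": alpha},
    )


def fit_cost_model(y, trd, baseline, family: str = "gamma_log",
                   outcome: str = "cost", year: int = 1) -> ModelResult:
    """Adjusted cost comparison: log-link gamma GLM or linear-normal model.

    The gamma family needs strictly positive responses; exact zeros are
    shifted up by half the smallest positive cost observed, and the count
    of shifted observations is reported.
    """
    y = np.asarray(y, dtype=float)
    trd = np.asarray(trd, dtype=float)
    if (y < 0).any():
        raise ValueError("negative costs encountered")
    X = _model_frame(trd, baseline)
    zero_count = 0
    if family == "gamma_log":
        zeros = y == 0
        zero_count = int(zeros.sum())
        if zero_count:
            if zeros.all():
                raise ValueError("all costs are zero; gamma family not fittable")
            y = y + zeros * (y[~zeros].min() / 2.0)
        fit = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
    elif family == "linear_normal":
        fit = sm.OLS(y, X).fit()
    else:
        raise ValueError(f"unknown cost-model family: {family}")
    m1, m0 = _recycled_means(fit, X)
    return ModelResult(
        outcome=outcome, year=year, family=family,
        mean_trd=m1, mean_control=m0, difference=m1 - m0, ratio=m1 / m0,
        n_trd=int(trd.sum()), n_control=int((1 - trd).sum()),
        extra={"zero_costs_shifted": zero_count},
    )


def bootstrap_difference(estimator, data: pd.DataFrame, iterations: int = 1000,
                         seed: int | None = None, arm_col: str = "trd",
                         max_failure_fraction: float = 0.10):
    """Percentile 95% CI of ``estimator`` over within-arm patient resamples.

    ``estimator`` maps a resampled patient-level DataFrame to a float. A
    resample on which the estimator raises is redrawn (the count is
    reported); more than ``max_failure_fraction`` failures aborts.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    arms = [data[data[arm_col].astype(bool)], data[~data[arm_col].astype(bool)]]
    max_failures = int(np.ceil(max_failure_fraction * iterations))
    stats, failures = [], 0
    while len(stats) < iterations:
        resample = pd.concat(
            [arm.iloc[rng.integers(0, len(arm), size=len(arm))] for arm in arms],
            ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stats.append(float(estimator(resample)))
        except Exception:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"bootstrap estimator failed on {failures} resamples "
                    f"(> {max_failure_fraction:.0%} of {iterations})")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi), failures


def fit_repeated_logistic(long: pd.DataFrame, outcome: str,
                          cov_struct: str = "exchangeable") -> list:
    """Per-year odds ratios for a binary outcome from a GEE logistic model.

    ``long`` needs one row per patient-year with columns ``patient_id``,
    ``year`` (1/2), ``y``, ``trd``, ``baseline``, ``elixhauser``. The model
    is y ~ trd + year2 + trd:year2 + baseline + elixhauser with the chosen
    working correlation and robust (sandwich) standard errors; the year-1
    OR is exp(b_trd), the year-2 OR is exp(b_trd + b_interaction) with a
    delta-method CI.
    """
    for year in (1, 2):
        sub = long[long["year"] == year]["y"]
        if sub.nunique() < 2:
            raise ValueError(f"outcome '{outcome}' is constant in follow-up year {year}")
    df = long.sort_values(["patient_id", "year"], kind="mergesort").copy()
    X = pd.DataFrame({
        "const": 1.0,
        "trd": df["trd"].astype(float).to_numpy(),
        "year2": (df["year"] == 2).astype(float).to_numpy(),
        "baseline": df["baseline"].astype(float).to_numpy(),
        "elixhauser": df["elixhauser"].astype(float).to_numpy(),
    })
    X["trd_x_year2"] = X["trd"] * X["year2"]
    struct = {"exchangeable": sm.cov_struct.Exchangeable,
              "independence": sm.cov_struct.Independence}[cov_struct]()
    model = sm.GEE(df["y"].astype(float).to_numpy(), X,
                   groups=df["patient_id"].to_numpy(),
                   family=sm.families.Binomial(), cov_struct=struct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    params, cov = fit.params, fit.cov_params()
    b_trd, b_int = params["trd"], params["trd_x_year2"]
    v_trd = cov.loc["trd", "trd"]
    v_year2 = v_trd + cov.loc["trd_x_year2", "trd_x_year2"] + 2 * cov.loc["trd", "trd_x_year2"]
    z = 1.959963984540054
    results = []
    for year, logor, var in ((1, b_trd, v_trd), (2, b_trd + b_int, v_year2)):
        se = float(np.sqrt(var))
        n1 = int(df.loc[(df["year"] == year) & (df["trd"].astype(bool)), "patient_id"].nunique())
        n0 = int(df.loc[(df["year"] == year) & (~df["trd"].astype(bool)), "patient_id"].nunique())
        results.append(ModelResult(
            outcome=outcome, year=year, family=f"gee_logistic_{cov_struct}",
            mean_trd=float("nan"), mean_control=float("nan"),
            difference=float(logor), odds_ratio=float(np.exp(logor)),
            ci_low=float(np.exp(logor - z * se)), ci_high=float(np.exp(logor + z * se)),
            n_trd=n1, n_control=n0,
            extra={"log_or_se": se},
        ))
    return results


def subgroup_costs_by_diagnosis(wide: pd.DataFrame, outcome_col: str = "y1_total_healthcare",
                                baseline_col: str = "base_total_healthcare",
                                family: str = "linear_normal"):
    """Cost model per depression diagnosis category (linear-normal family).

    Subgroups with fewer than 2 patients in either arm are skipped with a
    recorded reason. Returns (results by category, skip records).
    """
    results, skips = {}, []
    for cat, sub in wide.groupby("diagnosis_category"):
        n1 = int(sub["trd"].astype(bool).sum())
        n0 = int((~sub["trd"].astype(bool)).sum())
        if min(n1, n0) < 2:
            skips.append({"category": cat, "reason": f"too few patients (trd={n1}, control={n0})"})
            continue
        res = fit_cost_model(sub[outcome_col], sub["trd"], sub[baseline_col],
                             family=family, outcome=outcome_col, year=1)
        results[cat] = res
    return results, skips
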