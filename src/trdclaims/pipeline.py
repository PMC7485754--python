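"""End-to-end driver: simulate → cohort → classify → match → model → report.

Runs the full claims analysis on a generated bundle and returns every
intermediate product. All randomness flows from the simulation config's
seed plus the bootstrap seed, so two runs with identical arguments produce
byte-identical report files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import build_cohort
from .config import DEFAULT_DOSE_TABLE
from .matching import (
    build_covariate_table,
    fit_propensity,
    greedy_match,
    verify_matched_cohort,
)
from .outcomes import (
    annualize_outcomes,
    bootstrap_difference,
    fit_cost_model,
    fit_count_model,
    fit_repeated_logistic,
    pivot_outcomes,
    subgroup_costs_by_diagnosis,
)
from .regimens import classify_cohort
from .reports import balance_table, render_reports, results_table
from .synthetic import ClaimsBundle, SimulationConfig, generate_claims


@dataclass
class PipelineResult:
    bundle: ClaimsBundle
    cohort: pd.DataFrame          # with trd labels
    disposition: dict
    covariates: pd.DataFrame
    matched: object               # MatchedCohort
    analysis: pd.DataFrame        # wide per-patient outcome table (matched set)
    count_results: list = field(default_factory=list)
    cost_results: list = field(default_factory=list)
    or_results: list = field(default_factory=list)
    subgroup_results: dict = field(default_factory=dict)
    subgroup_skips: list = field(default_factory=list)


def build_analysis_table(cohort: pd.DataFrame, covariates: pd.DataFrame,
                         bundle: ClaimsBundle, matched) -> pd.DataFrame:
    """Wide outcome table for the matched set, with labels and covariates."""
    keep = set(matched.case_ids) | set(matched.control_ids)
    sub = cohort[cohort["patient_id"].isin(keep)]
    annual = annualize_outcomes(sub, bundle.medical_claims, bundle.pharmacy_claims)
    wide = pivot_outcomes(annual)
    wide = wide.merge(sub[["patient_id", "trd", "diagnosis_category"]], on="patient_id")
    wide = wide.merge(covariates[["patient_id", "elixhauser"]], on="patient_id")
    return wide.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def _or_long(wide: pd.DataFrame, outcome: str) -> pd.DataFrame:
    rows = []
    for year in (1, 2):
        rows.append(pd.DataFrame({
            "patient_id": wide["patient_id"],
            "year": year,
            "y": wide[f"y{year}_{outcome}"].astype(int),
            "trd": wide["trd"].astype(int),
            "baseline": wide[f"base_{outcome}"].astype(int),
            "elixhauser": wide["elixhauser"],
        }))
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: SimulationConfig, bootstrap_iterations: int = 1000,
                 bootstrap_seed: int = 0, outdir=None,
                 count_outcomes=("outpatient_visits", "hospital_los"),
                 cost_outcomes=("total_healthcare",)) -> PipelineResult:
    """Run the whole analysis; optionally render report files under outdir."""
    bundle = generate_claims(config)
    cohort, disposition = build_cohort(
        bundle.patients, bundle.pharmacy_claims, bundle.medical_claims,
        bundle.enrollment, windows=config.study_window)
    cohort = classify_cohort(cohort, bundle.pharmacy_claims, DEFAULT_DOSE_TABLE,
                             gap_days=config.study_window.episode_gap_days)
    covariates = build_covariate_table(cohort, bundle.medical_claims,
                                       windows=config.study_window)
    trd = pd.Series(cohort["trd"].to_numpy(),
                    index=pd.Index(cohort["patient_id"], name="patient_id"))
    ps = fit_propensity(covariates, cohort["trd"])
    matched = greedy_match(ps.scores, trd)
    verify_matched_cohort(matched, ps.scores, trd)
    analysis = build_analysis_table(cohort, covariates, bundle, matched)

    result = PipelineResult(bundle=bundle, cohort=cohort, disposition=disposition,
                            covariates=covariates, matched=matched, analysis=analysis)

    boot_seed = bootstrap_seed
    for outcome in count_outcomes:
        for year in (1, 2):
            ycol, bcol = f"y{year}_{outcome}", f"base_{outcome}"
            res = fit_count_model(analysis[ycol], analysis["trd"], analysis[bcol],
                                  outcome=outcome, year=year)
            est = lambda df, y=ycol, b=bcol, o=outcome, yr=year: fit_count_model(
                df[y], df["trd"], df[b], outcome=o, year=yr).difference
            lo, hi, _ = bootstrap_difference(est, analysis, bootstrap_iterations,
                                             seed=boot_seed)
            res.ci_low, res.ci_high = lo, hi
            res.bootstrap_iterations, res.seed = bootstrap_iterations, boot_seed
            result.count_results.append(res)
            boot_seed += 1
    for outcome in cost_outcomes:
        for year in (1, 2):
            ycol, bcol = f"y{year}_{outcome}", f"base_{outcome}"
            res = fit_cost_model(analysis[ycol], analysis["trd"], analysis[bcol],
                                 family="gamma_log", outcome=outcome, year=year)
            est = lambda df, y=ycol, b=bcol, o=outcome, yr=year: fit_cost_model(
                df[y], df["trd"], df[b], outcome=o, year=yr).difference
            lo, hi, _ = bootstrap_difference(est, analysis, bootstrap_iterations,
                                             seed=boot_seed)
            res.ci_low, res.ci_high = lo, hi
            res.bootstrap_iterations, res.seed = bootstrap_iterations, boot_seed
            result.cost_results.append(res)
            # linear-normal sensitivity fit (point estimates only)
            result.cost_results.append(
                fit_cost_model(analysis[ycol], analysis["trd"], analysis[bcol],
                               family="linear_normal", outcome=outcome, year=year))
            boot_seed += 1
    for outcome in ("any_ed", "any_hospitalization"):
        result.or_results.extend(fit_repeated_logistic(_or_long(analysis, outcome), outcome))
    result.subgroup_results, result.subgroup_skips = subgroup_costs_by_diagnosis(analysis)

    if outdir is not None:
        outdir = Path(outdir)
        matched_ids = set(matched.case_ids) | set(matched.control_ids)
        cov_labeled = covariates.merge(cohort[["patient_id", "trd"]], on="patient_id")
        balance = balance_table(cov_labeled.drop(columns="trd"), cov_labeled["trd"],
                                matched_ids)
        util = results_table(result.count_results + result.or_results)
        costs = results_table(
            result.cost_results
            + [r for _, r in sorted(result.subgroup_results.items())])
        render_reports(outdir, balance, util, costs)
        (outdir / "disposition.json").write_text(json.dumps(disposition, indent=2, sort_keys=True))
        (outdir / "provenance.json").write_text(json.dumps({
            "config_hash": config.digest(),
            "simulation_seed": config.seed,
            "bootstrap_seed": bootstrap_seed,
            "bootstrap_iterations": bootstrap_iterations,
            "n_eligible": int(len(cohort)),
            "n_trd": int(cohort["trd"].sum()),
            "n_matched_cases": len(matched.case_ids),
            "n_matched_controls": len(matched.control_ids),
        }, indent=2, sort_keys=True))
        matched.to_frame().to_csv(outdir / "matched_pairs.csv", index=False)
    return result
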