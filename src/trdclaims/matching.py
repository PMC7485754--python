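"""Baseline covariates, Elixhauser score, propensity model, greedy matching.

The propensity score is the modelled probability of TRD status given age at
index, sex, diagnosis category, four baseline psychiatric comorbidity flags
(anxiety, personality disorder, substance abuse, PTSD) and the Elixhauser
comorbidity count. Cases are matched to controls 1:4 (variable ratio,
without replacement) by sequential greedy nearest-neighbour matching inside
a caliper of width 0.02 on the probability scale, boundary inclusive.

Greedy matching output depends on processing order; cases are processed in
descending propensity score, ties broken by patient id, so the result is a
deterministic function of the inputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    DIAGNOSIS_CATEGORIES,
    ELIXHAUSER_CATEGORIES,
    MATCH_CALIPER,
    MATCH_RATIO,
    CodeLists,
    StudyWindows,
    _norm,
)
from .cohort import _dates, _split_codes

AGE_BINS = ((18, 24), (25, 34), (35, 44), (45, 54), (55, 63))

#: numerical slack for the inclusive caliper comparison on float scores
_CALIPER_TOL = 1e-9

PROPENSITY_COVARIATES = [
    "age_at_index", "female", "dx_300", "dx_309", "dx_311",
    "anxiety", "personality_disorder", "substance_abuse", "ptsd", "elixhauser",
]


def compute_elixhauser(baseline_claims: pd.DataFrame, category_map: dict | None = None) -> int:
    """Count distinct comorbidity categories hit by baseline diagnosis codes.

    One point per category with at least one matching code in the baseline
    window, independent of how many codes fall in the category; range 0–30
    with the shipped 30-category map.
    """
    category_map = category_map or ELIXHAUSER_CATEGORIES
    codes = {
        _norm(c)
        for cell in baseline_claims["icd_codes"]
        for c in _split_codes(cell)
    }
    score = 0
    for prefixes in category_map.values():
        if any(code.startswith(tuple(prefixes)) for code in codes):
            score += 1
    return score


def age_group(age: int) -> str:
    for lo, hi in AGE_BINS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} outside the 18-63 study range")


def extract_baseline_covariates(record: dict, medical_claims: pd.DataFrame,
                                code_lists: CodeLists, windows: StudyWindows,
                                category_map: dict | None = None) -> dict:
    """Covariate row for one cohort member (flags from the 365-day baseline)."""
    index_date = record["index_date"]
    lo = index_date - dt.timedelta(days=windows.baseline_days)
    mdates = _dates(medical_claims["service_start"])
    base = medical_claims[(mdates >= lo) & (mdates < index_date)]

    def flag(prefixes) -> bool:
        return any(
            _norm(c).startswith(prefixes)
            for cell in base["icd_codes"]
            for c in _split_codes(cell)
        )

    return {
        "patient_id": record["patient_id"],
        "age_at_index": int(record["age_at_index"]),
        "age_group": age_group(int(record["age_at_index"])),
        "female": int(record["sex"] == "female"),
        "index_year": int(record["index_year"]),
        "diagnosis_category": record["diagnosis_category"],
        "anxiety": int(flag(code_lists.anxiety_prefixes)),
        "personality_disorder": int(flag(code_lists.personality_prefixes)),
        "substance_abuse": int(flag(code_lists.substance_prefixes)),
        "ptsd": int(flag(code_lists.ptsd_prefixes)),
        "elixhauser": compute_elixhauser(base, category_map),
    }


def build_covariate_table(cohort: pd.DataFrame, medical_claims: pd.DataFrame,
                          code_lists: CodeLists | None = None,
                          windows: StudyWindows | None = None,
                          category_map: dict | None = None) -> pd.DataFrame:
    code_lists = code_lists or CodeLists()
    windows = windows or StudyWindows()
    by_patient = dict(tuple(medical_claims.groupby("patient_id", sort=False)))
    empty = medical_claims.iloc[0:0]
    rows = [
        extract_baseline_covariates(rec, by_patient.get(rec["patient_id"], empty),
                                    code_lists, windows, category_map)
        for rec in cohort.to_dict("records")
    ]
    return pd.DataFrame(rows)


def _design(cov: pd.DataFrame) -> pd.DataFrame:
    X = cov[["age_at_index", "female", "anxiety", "personality_disorder",
             "substance_abuse", "ptsd", "elixhauser"]].astype(float).copy()
    for cat in DIAGNOSIS_CATEGORIES[1:]:  # 296.X is the reference level
        X[f"dx_{cat[:3]}"] = (cov["diagnosis_category"] == cat).astype(float)
    return sm.add_constant(X[["age_at_index", "female", "dx_300", "dx_309", "dx_311",
                              "anxiety", "personality_disorder", "substance_abuse",
                              "ptsd", "elixhauser"]], has_constant="add")


@dataclass
class PropensityModel:
    params: pd.Series
    scores: pd.Series  # indexed by patient_id, values in (0, 1)


def fit_propensity(covariates: pd.DataFrame, trd: pd.Series) -> PropensityModel:
    """Logistic regression of TRD status on the baseline covariates."""
    y = np.asarray(trd).astype(float)
    if y.min() == y.max():
        raise ValueError("propensity model requires both TRD and non-TRD patients")
    X = _design(covariates)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    p = np.asarray(fit.predict(X))
    if not ((p > 0).all() and (p < 1).all()):
        extremes = X.columns[np.abs(fit.params.values).argmax()]
        raise ValueError(f"propensity scores degenerate (separation?); largest coefficient: {extremes}")
    scores = pd.Series(p, index=pd.Index(covariates["patient_id"], name="patient_id"))
    return PropensityModel(params=fit.params, scores=scores)


@dataclass
class MatchedCohort:
    matches: list                       # (case_id, [control_ids...])
    unmatched_case_ids: list
    ratio: int = MATCH_RATIO
    caliper: float = MATCH_CALIPER
    pair_distances: dict = field(default_factory=dict)  # (case, control) -> distance

    @property
    def case_ids(self) -> list:
        return [c for c, _ in self.matches]

    @property
    def control_ids(self) -> list:
        return [g for _, grp in self.matches for g in grp]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"case_id": c, "control_id": g, "pair_distance": self.pair_distances[(c, g)]}
            for c, grp in self.matches
            for g in grp
        ]
        return pd.DataFrame(rows, columns=["case_id", "control_id", "pair_distance"])


def greedy_match(scores: pd.Series, trd: pd.Series, ratio: int = MATCH_RATIO,
                 caliper: float = MATCH_CALIPER, seed: int | None = None) -> MatchedCohort:
    """Sequential greedy 1:`ratio` caliper matching without replacement.

    Cases are processed in descending score (ties by patient id); each takes
    its up-to-`ratio` nearest still-unmatched controls within the caliper
    (distance ties broken by control id). Cases with no in-caliper control
    are reported unmatched. `seed` is reserved for an optional randomized
    processing order and does not affect the default deterministic order.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    trd = pd.Series(np.asarray(trd, dtype=bool), index=scores.index)
    cases = scores[trd].sort_index().sort_values(ascending=False, kind="mergesort")
    ctrl = scores[~trd].sort_index()
    ctrl_ids = np.asarray(ctrl.index)
    ctrl_scores = ctrl.to_numpy(dtype=float)
    available = np.ones(len(ctrl), dtype=bool)

    matches, unmatched, distances = [], [], {}
    for case_id, s in cases.items():
        d = np.abs(ctrl_scores - s)
        ok = available & (d <= caliper + _CALIPER_TOL)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            unmatched.append(case_id)
            continue
        order = idx[np.lexsort((ctrl_ids[idx], d[idx]))][:ratio]
        taken = list(ctrl_ids[order])
        available[order] = False
        matches.append((case_id, taken))
        for g, j in zip(taken, order):
            distances[(case_id, g)] = float(d[j])
    return MatchedCohort(matches=matches, unmatched_case_ids=unmatched,
                         ratio=ratio, caliper=caliper, pair_distances=distances)


def verify_matched_cohort(mc: MatchedCohort, scores: pd.Series, trd: pd.Series) -> None:
    """Independent post-hoc check of every matching invariant; raises on violation."""
    trd = pd.Series(np.asarray(trd, dtype=bool), index=scores.index)
    seen = set()
    for case_id, grp in mc.matches:
        if not trd.loc[case_id]:
            raise AssertionError(f"case {case_id} is not a TRD patient")
        if not 1 <= len(grp) <= mc.ratio:
            raise AssertionError(f"case {case_id} has {len(grp)} controls")
        for g in grp:
            if trd.loc[g]:
                raise AssertionError(f"control {g} is a TRD patient")
            if g in seen:
                raise AssertionError(f"control {g} reused")
            seen.add(g)
            if abs(scores.loc[case_id] - scores.loc[g]) > mc.caliper + _CALIPER_TOL:
                raise AssertionError(f"pair ({case_id}, {g}) violates the caliper")
    overlap = seen & set(mc.case_ids)
    if overlap:
        raise AssertionError(f"ids appear as both case and control: {sorted(overlap)[:5]}")


def standardized_mean_differences(covariates: pd.DataFrame, trd: pd.Series,
                                  columns=None) -> pd.Series:
    """Absolute standardized mean differences (TRD vs non-TRD) per covariate."""
    columns = list(columns or PROPENSITY_COVARIATES)
    X = _design(covariates)[columns]
    t = np.asarray(trd, dtype=bool)
    m1, m0 = X[t].mean(), X[~t].mean()
    v1, v0 = X[t].var(ddof=1), X[~t].var(ddof=1)
    pooled = np.sqrt((v1 + v0) / 2.0)
    smd = (m1 - m0).abs() / pooled.replace(0.0, np.nan)
    return smd.fillna(0.0)
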