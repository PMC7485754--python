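"""Cohort construction: index dates, inclusion criteria, exclusions.

The cohort is anchored on the index date — the first antidepressant
dispensing inside the accrual window. Inclusion requires age 18–63 at
index, a 183-day pre-index washout free of depression-treatment claims, a
depression diagnosis within ±30 days of index, a second antidepressant
dispensing with a supply gap of at most 30 days, and continuous pharmacy +
medical enrollment over the 365-day baseline and 730-day follow-up
(required only through the death date for decedents). Exclusions remove
patients with psychosis/schizophrenia/mania/bipolar/dementia codes at any
time, or mood-stabilizer-type dispensings, ECT or TMS in the 183 days
before index.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .config import (
    ANTIDEPRESSANT,
    DIAGNOSIS_CATEGORIES,
    CodeLists,
    StudyWindows,
    _norm,
)

#: inclusion reason codes, in evaluation order
ELIGIBILITY_REASONS = ("age", "washout", "diagnosis_window", "refill", "enrollment")


@dataclass
class Decision:
    passed: bool
    reasons: list  # failed criteria, in evaluation order


def _dates(series) -> pd.Series:
    return pd.to_datetime(series).dt.date


def _split_codes(cell) -> list:
    if isinstance(cell, str):
        return [c for c in cell.split(";") if c]
    return list(cell) if cell is not None else []


def find_index_date(pharmacy_claims: pd.DataFrame, windows: StudyWindows):
    """Earliest antidepressant dispense date inside the accrual window, or None."""
    ad = pharmacy_claims[pharmacy_claims["drug_class"] == ANTIDEPRESSANT]
    if ad.empty:
        return None
    d = _dates(ad["dispense_date"])
    inside = d[(d >= windows.index_start) & (d <= windows.index_end)]
    return None if inside.empty else inside.min()


def _age_at(birth_date: dt.date, on: dt.date) -> int:
    return on.year - birth_date.year - ((on.month, on.day) < (birth_date.month, birth_date.day))


def _death_date(patient):
    death = patient.get("death_date")
    if death is None or (isinstance(death, str) and not death.strip()) or pd.isna(death):
        return None
    return pd.Timestamp(death).date()


def check_eligibility(patient, pharmacy_claims, medical_claims, enrollment,
                      index_date: dt.date, code_lists: CodeLists,
                      windows: StudyWindows) -> Decision:
    """Evaluate all inclusion criteria; returns pass/fail with reason codes."""
    reasons = []
    birth = pd.Timestamp(patient["birth_date"]).date()
    death = _death_date(patient)

    age = _age_at(birth, index_date)
    if not (18 <= age <= 63):
        reasons.append("age")

    washout_lo = index_date - dt.timedelta(days=windows.washout_days)
    pdates = _dates(pharmacy_claims["dispense_date"])
    in_washout = (pdates >= washout_lo) & (pdates < index_date)
    rx_hit = (pharmacy_claims["drug_class"].isin(code_lists.washout_drug_classes) & in_washout).any()
    mdates = _dates(medical_claims["service_start"])
    m_in_washout = (mdates >= washout_lo) & (mdates < index_date)
    proc_hit = any(
        set(_split_codes(p)) & code_lists.washout_procedures
        for p in medical_claims.loc[m_in_washout, "procedure_codes"]
    )
    if rx_hit or proc_hit:
        reasons.append("washout")

    w = dt.timedelta(days=windows.diagnosis_window_days)
    near = medical_claims[(mdates >= index_date - w) & (mdates <= index_date + w)]
    has_dx = any(
        any(code_lists.is_mdd(c) for c in _split_codes(codes))
        for codes in near["icd_codes"]
    )
    if not has_dx:
        reasons.append("diagnosis_window")

    ad_mask = (pharmacy_claims["drug_class"] == ANTIDEPRESSANT) & (pdates >= index_date)
    ad = pharmacy_claims[ad_mask].assign(_d=pdates[ad_mask]).sort_values("_d", kind="mergesort")
    if len(ad) < 2:
        reasons.append("refill")
    else:
        first = ad.iloc[0]
        supply_end = first["_d"] + dt.timedelta(days=int(first["days_supply"]) - 1)
        if (ad.iloc[1]["_d"] - supply_end).days > windows.refill_gap_days:
            reasons.append("refill")

    need_start = index_date - dt.timedelta(days=windows.baseline_days)
    need_end = index_date + dt.timedelta(days=windows.followup_days)
    if death is not None and death < need_end:
        need_end = death
    spells = enrollment[(enrollment["has_pharmacy"]) & (enrollment["has_medical"])]
    if not _covered(spells, need_start, need_end):
        reasons.append("enrollment")

    return Decision(passed=not reasons, reasons=reasons)


def _covered(spells: pd.DataFrame, lo: dt.date, hi: dt.date) -> bool:
    """True iff [lo, hi] is covered by the union of spells (1-day joins allowed)."""
    if spells.empty:
        return False
    ivs = sorted(
        (pd.Timestamp(s).date(), pd.Timestamp(e).date())
        for s, e in zip(spells["start"], spells["end"])
    )
    cursor = lo
    for s, e in ivs:
        if s > cursor + dt.timedelta(days=1):
            break
        if e >= cursor:
            cursor = max(cursor, e)
        if cursor >= hi:
            return True
    return cursor >= hi


def apply_exclusions(pharmacy_claims, medical_claims, code_lists: CodeLists,
                     index_date: dt.date, windows: StudyWindows) -> Decision:
    """Exclusion screen: dx codes at any time; drugs/procedures 183 days pre-index."""
    reasons = []
    any_dx = any(
        any(code_lists.is_exclusion_dx(c) for c in _split_codes(codes))
        for codes in medical_claims["icd_codes"]
    )
    if any_dx:
        reasons.append("exclusion_diagnosis")

    lo = index_date - dt.timedelta(days=windows.washout_days)
    pdates = _dates(pharmacy_claims["dispense_date"])
    pre = (pdates >= lo) & (pdates < index_date)
    if (pharmacy_claims["drug_class"].isin(code_lists.exclusion_drug_classes) & pre).any():
        reasons.append("exclusion_drug")
    mdates = _dates(medical_claims["service_start"])
    m_pre = (mdates >= lo) & (mdates < index_date)
    if any(
        set(_split_codes(p)) & code_lists.exclusion_procedures
        for p in medical_claims.loc[m_pre, "procedure_codes"]
    ):
        reasons.append("exclusion_procedure")
    return Decision(passed=not reasons, reasons=reasons)


def _diagnosis_category(medical_claims, index_date, code_lists, windows) -> str:
    """Category of the MDD code nearest the index date (ties: 296>300>309>311)."""
    w = dt.timedelta(days=windows.diagnosis_window_days)
    mdates = _dates(medical_claims["service_start"])
    near = medical_claims[(mdates >= index_date - w) & (mdates <= index_date + w)]
    best = None  # (abs offset, category priority, category)
    for row in near.itertuples():
        off = abs((pd.Timestamp(row.service_start).date() - index_date).days)
        for code in _split_codes(row.icd_codes):
            if code_lists.is_mdd(code):
                cat = code_lists.mdd_category(code)
                key = (off, DIAGNOSIS_CATEGORIES.index(cat))
                if best is None or key < best[0]:
                    best = (key, cat)
    if best is None:
        raise ValueError("no MDD diagnosis in window (eligibility not enforced?)")
    return best[1]


def build_cohort(patients, pharmacy_claims, medical_claims, enrollment,
                 code_lists: CodeLists | None = None,
                 windows: StudyWindows | None = None):
    """Apply all inclusion/exclusion rules to the claims tables.

    Returns ``(cohort, disposition)``: one row per eligible patient with its
    index date, age, sex, index year and diagnosis category, plus a
    disposition dict counting every failure reason (a patient is counted
    once, under its first failed criterion, so reason counts + eligible =
    total patients).
    """
    code_lists = code_lists or CodeLists()
    windows = windows or StudyWindows()
    known = set(patients["patient_id"])
    for name, tab in (("pharmacy", pharmacy_claims), ("medical", medical_claims),
                      ("enrollment", enrollment)):
        unknown = set(tab["patient_id"]) - known
        if unknown:
            raise ValueError(f"{name} claims reference unknown patients: {sorted(unknown)[:5]}")

    rx_by = dict(tuple(pharmacy_claims.groupby("patient_id", sort=False)))
    mx_by = dict(tuple(medical_claims.groupby("patient_id", sort=False)))
    en_by = dict(tuple(enrollment.groupby("patient_id", sort=False)))
    empty_rx = pharmacy_claims.iloc[0:0]
    empty_mx = medical_claims.iloc[0:0]
    empty_en = enrollment.iloc[0:0]

    rows, disposition = [], {"no_index_date": 0, "excluded": 0, "eligible": 0}
    for r in ELIGIBILITY_REASONS:
        disposition[f"fail_{r}"] = 0

    for patient in patients.to_dict("records"):
        pid = patient["patient_id"]
        rx = rx_by.get(pid, empty_rx)
        mx = mx_by.get(pid, empty_mx)
        en = en_by.get(pid, empty_en)
        index_date = find_index_date(rx, windows)
        if index_date is None:
            disposition["no_index_date"] += 1
            continue
        elig = check_eligibility(patient, rx, mx, en, index_date, code_lists, windows)
        if not elig.passed:
            disposition[f"fail_{elig.reasons[0]}"] += 1
            continue
        excl = apply_exclusions(rx, mx, code_lists, index_date, windows)
        if not excl.passed:
            disposition["excluded"] += 1
            continue
        disposition["eligible"] += 1
        rows.append(
            {
                "patient_id": pid,
                "index_date": index_date,
                "age_at_index": _age_at(pd.Timestamp(patient["birth_date"]).date(), index_date),
                "sex": patient["sex"],
                "index_year": index_date.year,
                "diagnosis_category": _diagnosis_category(mx, index_date, code_lists, windows),
                "death_date": _death_date(patient),
            }
        )
    cohort = pd.DataFrame(
        rows,
        columns=["patient_id", "index_date", "age_at_index", "sex", "index_year",
                 "diagnosis_category", "death_date"],
    )
    return cohort, disposition
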