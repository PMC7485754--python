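"""Treatment-episode construction and the TRD phenotyping algorithm.

A patient's antidepressant fills are assembled into one treatment episode
(a maximal run of drug-supply coverage starting at the index date, where
consecutive covered intervals are separated by no more than a configurable
gap), the episode is segmented into ordered regimens (lines of therapy), and
the patient is labelled treatment-resistant iff the episode contains at
least three regimens with the first two adequate in dose and duration.

Day-numbering convention: a regimen's start date is Day 1, so a drug added
on Day k starts k-1 days after the regimen start. "Adequate duration" is
operationalized by the failure rules themselves:

* switch failure — a new drug begins 29–180 days (inclusive) after the
  current regimen started, with no remaining supply of the current regimen's
  drugs on that date;
* augmentation failure — a new drug begins on Day 15 or later while the
  current regimen's supply is still active.

A switch outside the 29–180-day window still opens a new line of therapy
but does not mark the prior regimen as failed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .config import (
    ANTIDEPRESSANT,
    AUGMENT_FAIL_MIN_DAY,
    AUGMENTATION_CLASSES,
    SWITCH_FAIL_MAX_GAP_DAYS,
    SWITCH_FAIL_MIN_GAP_DAYS,
)


class Transition(Enum):
    SWITCH_FAILURE = "switch_failure"
    AUGMENTATION_FAILURE = "augmentation_failure"
    SAME_REGIMEN = "same_regimen"
    NO_FAILURE = "no_failure"


class FailureMode(Enum):
    SWITCH = "switch"
    AUGMENTATION = "augmentation"
    NONE = "none"


@dataclass
class Regimen:
    """One line of antidepressant therapy within a treatment episode."""

    line_number: int
    drugs: list                      # (drug_name, role) in start order
    start: dt.date
    end: dt.date
    dose_adequate: bool = False
    failure_mode: FailureMode = FailureMode.NONE

    @property
    def drug_names(self) -> set:
        return {name for name, _ in self.drugs}

    @property
    def antidepressants(self) -> list:
        return [n for n, role in self.drugs if role in ("core_antidepressant", "added_antidepressant")]


@dataclass
class TreatmentEpisode:
    """Maximal covered run of therapy starting at the index date."""

    patient_id: str
    start: dt.date
    end: dt.date
    claims: pd.DataFrame            # fills retained inside the episode
    regimens: list = field(default_factory=list)


@dataclass
class TrdResult:
    patient_id: str
    trd: bool
    n_regimens: int
    audit: list                     # one dict per regimen


def _as_date(x) -> dt.date:
    if isinstance(x, pd.Timestamp):
        return x.date()
    return x


def _coverage_intervals(claims: pd.DataFrame) -> list:
    """Inclusive (first_day, last_day) supply intervals, one per fill."""
    out = []
    for row in claims.itertuples():
        start = _as_date(row.dispense_date)
        out.append((start, start + dt.timedelta(days=int(row.days_supply) - 1)))
    return out


def _covers(intervals, day: dt.date) -> bool:
    return any(a <= day <= b for a, b in intervals)


def classify_drug_transition(regimen_start: dt.date, prior_drug_coverage, new_drug_start: dt.date) -> Transition:
    """Classify the start of a new drug relative to the current regimen.

    Parameters
    ----------
    regimen_start : date
        Day 1 of the current regimen.
    prior_drug_coverage : iterable of (date, date)
        Inclusive days-supply intervals of the current regimen's drugs.
    new_drug_start : date
        First dispense date of the drug not yet in the regimen.

    Returns
    -------
    Transition
        ``SAME_REGIMEN`` (combination formed within the first 14 days),
        ``AUGMENTATION_FAILURE`` (added on Day 15+ under active supply),
        ``SWITCH_FAILURE`` (non-overlapping start 29–180 days in), or
        ``NO_FAILURE`` (non-overlapping start outside that window).
    """
    regimen_start = _as_date(regimen_start)
    new_drug_start = _as_date(new_drug_start)
    gap = (new_drug_start - regimen_start).days
    if gap < 0:
        raise ValueError("new drug starts before the current regimen")
    if _covers(prior_drug_coverage, new_drug_start):
        day_number = gap + 1
        if day_number >= AUGMENT_FAIL_MIN_DAY:
            return Transition.AUGMENTATION_FAILURE
        return Transition.SAME_REGIMEN
    if SWITCH_FAIL_MIN_GAP_DAYS <= gap <= SWITCH_FAIL_MAX_GAP_DAYS:
        return Transition.SWITCH_FAILURE
    return Transition.NO_FAILURE


def build_treatment_episode(pharmacy_claims: pd.DataFrame, index_date: dt.date,
                            gap_days: int = 180) -> TreatmentEpisode:
    """Assemble the current-episode fills for one patient.

    The episode is the maximal run of antidepressant/augmentation coverage
    beginning at ``index_date`` in which each successive fill starts no more
    than ``gap_days`` after the coverage accumulated so far ends. Fills
    beyond the first larger gap belong to a later episode and are dropped.
    """
    index_date = _as_date(index_date)
    claims = pharmacy_claims[
        pharmacy_claims["drug_class"].isin({ANTIDEPRESSANT} | AUGMENTATION_CLASSES)
    ].copy()
    claims["dispense_date"] = pd.to_datetime(claims["dispense_date"])
    claims = claims[claims["dispense_date"].dt.date >= index_date]
    claims = claims.sort_values(["dispense_date", "drug_name"], kind="mergesort").reset_index(drop=True)

    on_index = claims[
        (claims["dispense_date"].dt.date == index_date)
        & (claims["drug_class"] == ANTIDEPRESSANT)
    ]
    if on_index.empty:
        raise ValueError(f"no antidepressant dispensing on the index date {index_date}")

    kept, coverage_end = [], None
    for row in claims.itertuples():
        start = _as_date(row.dispense_date)
        end = start + dt.timedelta(days=int(row.days_supply) - 1)
        if coverage_end is None or (start - coverage_end).days <= gap_days:
            kept.append(row.Index)
            coverage_end = end if coverage_end is None else max(coverage_end, end)
        else:
            break
    episode_claims = claims.loc[kept].reset_index(drop=True)
    patient_id = str(episode_claims["patient_id"].iloc[0])
    return TreatmentEpisode(patient_id=patient_id, start=index_date,
                            end=coverage_end, claims=episode_claims)


def assess_adequate_dose(regimen: Regimen, episode_claims: pd.DataFrame, dose_table: dict) -> bool:
    """True iff any antidepressant in the regimen reaches its minimum dose.

    A fill counts if it is dispensed inside the regimen's date span at a
    daily dose at or above the drug's table minimum (boundary inclusive);
    titration from below to above the minimum mid-regimen therefore counts.
    """
    ads = regimen.antidepressants
    missing = [d for d in ads if d not in dose_table]
    if missing:
        raise KeyError(f"no minimum-dose entry for drug(s): {', '.join(sorted(missing))}")
    dates = pd.to_datetime(episode_claims["dispense_date"]).dt.date
    for drug in ads:
        sel = episode_claims[
            (episode_claims["drug_name"] == drug)
            & (dates >= regimen.start) & (dates <= regimen.end)
        ]
        if (sel["daily_dose"] >= dose_table[drug]).any():
            return True
    return False


def _build_regimens(episode: TreatmentEpisode) -> list:
    """Segment the episode's fills into ordered lines of therapy."""
    claims = episode.claims
    dates = pd.to_datetime(claims["dispense_date"]).dt.date
    # first start date per drug = a drug-start event; refills are ignored
    firsts = (
        claims.assign(_d=dates)
        .groupby("drug_name", sort=False)
        .agg(start=("_d", "min"), drug_class=("drug_class", "first"))
        .reset_index()
        .sort_values(["start", "drug_name"], kind="mergesort")
    )

    def drug_coverage(names):
        # all fills of the regimen's drugs: supply dispensed before the
        # regimen opened can still be active (augmentation carry-over)
        sel = claims[claims["drug_name"].isin(names)]
        return _coverage_intervals(sel)

    regimens: list = []
    current: Regimen | None = None
    for ev in firsts.itertuples():
        role = "core_antidepressant" if ev.drug_class == ANTIDEPRESSANT else "augmentation"
        if current is None:
            if ev.drug_class != ANTIDEPRESSANT:
                continue  # the first regimen must be founded by an antidepressant
            current = Regimen(line_number=1, drugs=[(ev.drug_name, role)],
                              start=ev.start, end=episode.end)
            continue
        if ev.drug_name in current.drug_names:
            continue
        coverage = drug_coverage(current.drug_names)
        kind = classify_drug_transition(current.start, coverage, ev.start)
        if kind is Transition.SAME_REGIMEN:
            if role == "core_antidepressant":
                role = "added_antidepressant"
            current.drugs.append((ev.drug_name, role))
        elif kind is Transition.AUGMENTATION_FAILURE:
            current.failure_mode = FailureMode.AUGMENTATION
            current.end = ev.start - dt.timedelta(days=1)
            regimens.append(current)
            carried = [(n, "core_antidepressant" if r == "core_antidepressant" else r)
                       for n, r in current.drugs]
            new_role = "added_antidepressant" if ev.drug_class == ANTIDEPRESSANT else "augmentation"
            current = Regimen(line_number=current.line_number + 1,
                              drugs=carried + [(ev.drug_name, new_role)],
                              start=ev.start, end=episode.end)
        else:
            # non-overlapping start: a new line opens whether or not the
            # prior one counts as failed
            if ev.drug_class != ANTIDEPRESSANT:
                continue  # a lapsed supply cannot be augmented; not a new core
            current.failure_mode = (
                FailureMode.SWITCH if kind is Transition.SWITCH_FAILURE else FailureMode.NONE
            )
            current.end = ev.start - dt.timedelta(days=1)
            regimens.append(current)
            current = Regimen(line_number=current.line_number + 1,
                              drugs=[(ev.drug_name, "core_antidepressant")],
                              start=ev.start, end=episode.end)
    if current is not None:
        regimens.append(current)
    return regimens


def classify_trd(episode: TreatmentEpisode, dose_table: dict) -> TrdResult:
    """Label one treatment episode as TRD or non-TRD, with an audit trail.

    TRD requires at least three regimens in the episode, with regimens 1 and
    2 each (a) reaching an adequate dose and (b) ending in a switch or
    augmentation failure (the adequate-duration operationalization). The
    third regimen needs no adequacy assessment; its initiation completes the
    definition.
    """
    regimens = _build_regimens(episode)
    for reg in regimens:
        reg.dose_adequate = assess_adequate_dose(reg, episode.claims, dose_table)
    episode.regimens = regimens

    def failed_adequately(reg: Regimen) -> bool:
        return reg.dose_adequate and reg.failure_mode is not FailureMode.NONE

    trd = len(regimens) >= 3 and failed_adequately(regimens[0]) and failed_adequately(regimens[1])
    audit = [
        {
            "line": reg.line_number,
            "drugs": [list(d) for d in reg.drugs],
            "start": reg.start.isoformat(),
            "end": reg.end.isoformat(),
            "dose_adequate": bool(reg.dose_adequate),
            "failure_mode": reg.failure_mode.value,
        }
        for reg in regimens
    ]
    return TrdResult(patient_id=episode.patient_id, trd=bool(trd),
                     n_regimens=len(regimens), audit=audit)


def classify_cohort(cohort: pd.DataFrame, pharmacy_claims: pd.DataFrame,
                    dose_table: dict, gap_days: int = 180) -> pd.DataFrame:
    """Run the TRD classifier for every cohort member.

    Returns the cohort table with ``trd``, ``n_regimens`` and a JSON-ready
    ``audit`` column attached.
    """
    by_patient = dict(tuple(pharmacy_claims.groupby("patient_id", sort=False)))
    labels, n_regs, audits = [], [], []
    for row in cohort.itertuples():
        claims = by_patient.get(row.patient_id)
        episode = build_treatment_episode(claims, row.index_date, gap_days=gap_days)
        res = classify_trd(episode, dose_table)
        labels.append(res.trd)
        n_regs.append(res.n_regimens)
        audits.append(res.audit)
    out = cohort.copy()
    out["trd"] = labels
    out["n_regimens"] = n_regs
    out["audit"] = audits
    return out
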