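"""Shared builders for toy claims fixtures (all dates offset from one index)."""

import datetime as dt

import pandas as pd
import pytest

INDEX_DATE = dt.date(2013, 3, 1)

RX_COLUMNS = ["patient_id", "dispense_date", "drug_name", "drug_class",
              "daily_dose", "days_supply", "payer_cost", "patient_cost"]
MED_COLUMNS = ["patient_id", "service_start", "service_end", "setting",
               "icd_codes", "procedure_codes", "payer_cost", "patient_cost"]
ENROLL_COLUMNS = ["patient_id", "start", "end", "has_pharmacy", "has_medical"]


def day(offset: int, anchor: dt.date = INDEX_DATE) -> str:
    return (anchor + dt.timedelta(days=offset)).isoformat()


def rx(pid="P1", offset=0, drug="sertraline", drug_class="antidepressant",
       dose=50.0, supply=30, payer=10.0, patient=2.0):
    return dict(patient_id=pid, dispense_date=day(offset), drug_name=drug,
                drug_class=drug_class, daily_dose=dose, days_supply=supply,
                payer_cost=payer, patient_cost=patient)


def rx_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=RX_COLUMNS)


def med(pid="P1", offset=0, icd="3004", setting="outpatient", end_offset=None,
        proc="", payer=100.0, patient=20.0):
    return dict(patient_id=pid, service_start=day(offset),
                service_end=day(offset if end_offset is None else end_offset),
                setting=setting, icd_codes=icd, procedure_codes=proc,
                payer_cost=payer, patient_cost=patient)


def med_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=MED_COLUMNS)


def enroll(pid="P1", start_offset=-400, end_offset=760):
    return dict(patient_id=pid, start=day(start_offset), end=day(end_offset),
                has_pharmacy=True, has_medical=True)


def enroll_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=ENROLL_COLUMNS)


def patient(pid="P1", age=40, sex="female", death_offset=None):
    birth = INDEX_DATE - dt.timedelta(days=age * 365 + 100)
    return dict(patient_id=pid, birth_date=birth.isoformat(), sex=sex,
                death_date=day(death_offset) if death_offset is not None else "")


@pytest.fixture(scope="session")
def small_bundle():
    """One shared 600-patient bundle for cross-stage tests."""
    from trdclaims import SimulationConfig, generate_claims
    return generate_claims(SimulationConfig(n_patients=600, seed=123))
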