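#!/usr/bin/env python
"""Run the regimen-failure TRD phenotyping algorithm over the cohort:
build each patient's treatment episode from antidepressant fills, segment
it into lines of therapy via the 29-180-day switch and Day-15 augmentation
rules, and label TRD (3+ regimens, first two adequate in dose/duration).

Writes the labelled cohort and a JSON audit trail of every regimen.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from trdclaims import read_bundle
from trdclaims.config import DEFAULT_DOSE_TABLE, load_dose_table
from trdclaims.regimens import classify_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--doses", type=Path, default=None, help="YAML dose table override")
    ap.add_argument("--out", type=Path, default=Path("results/trd.csv"))
    ap.add_argument("--audit", type=Path, default=Path("results/trd_audit.json"))
    args = ap.parse_args()

    bundle = read_bundle(args.data)
    cohort = pd.read_csv(args.cohort)
    cohort["index_date"] = pd.to_datetime(cohort["index_date"]).dt.date
    doses = load_dose_table(args.doses) if args.doses else DEFAULT_DOSE_TABLE

    labelled = classify_cohort(cohort, bundle.pharmacy_claims, doses,
                               gap_days=bundle.config.study_window.episode_gap_days)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.audit.write_text(json.dumps(
        {row.patient_id: row.audit for row in labelled.itertuples()}, indent=1))
    labelled.drop(columns="audit").to_csv(args.out, index=False)

    n_trd = int(labelled["trd"].sum())
    print(f"{n_trd} of {len(labelled)} cohort patients classified TRD "
          f"({n_trd / len(labelled):.1%})")
    print("regimen-count distribution:",
          labelled["n_regimens"].value_counts().sort_index().to_dict())
    if "is_trd" in bundle.ground_truth:
        merged = labelled.merge(bundle.ground_truth[["patient_id", "is_trd"]],
                                on="patient_id")
        agreement = (merged["trd"] == merged["is_trd"]).mean()
        print(f"agreement with scripted ground truth: {agreement:.4f}")
    print(f"labels -> {args.out}; audit -> {args.audit}")


if __name__ == "__main__":
    main()
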