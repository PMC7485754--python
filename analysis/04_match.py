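#!/usr/bin/env python
"""Compute baseline covariates and the Elixhauser score, fit the propensity
model (TRD status on age, sex, diagnosis category, psychiatric comorbidity
flags, Elixhauser), and greedily match cases to controls 1:4 within a 0.02
caliper, without replacement.

Writes the matched pairs and a pre/post-matching balance table.
"""

import argparse
from pathlib import Path

import pandas as pd

from trdclaims import (
    build_covariate_table,
    fit_propensity,
    greedy_match,
    read_bundle,
    verify_matched_cohort,
)
from trdclaims.reports import balance_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--cohort", type=Path, default=Path("results/trd.csv"))
    ap.add_argument("--ratio", type=int, default=4)
    ap.add_argument("--caliper", type=float, default=0.02)
    ap.add_argument("--out", type=Path, default=Path("results/matched.csv"))
    ap.add_argument("--balance", type=Path, default=Path("results/balance.csv"))
    args = ap.parse_args()

    bundle = read_bundle(args.data)
    cohort = pd.read_csv(args.cohort)
    cohort["index_date"] = pd.to_datetime(cohort["index_date"]).dt.date

    covariates = build_covariate_table(cohort, bundle.medical_claims,
                                       windows=bundle.config.study_window)
    model = fit_propensity(covariates, cohort["trd"])
    labels = pd.Series(cohort["trd"].to_numpy(), index=model.scores.index)
    matched = greedy_match(model.scores, labels, ratio=args.ratio, caliper=args.caliper)
    verify_matched_cohort(matched, model.scores, labels)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    matched.to_frame().to_csv(args.out, index=False)
    ids = set(matched.case_ids) | set(matched.control_ids)
    balance = balance_table(covariates, cohort["trd"], ids)
    balance.to_csv(args.balance, index=False, float_format="%.6g")

    print(f"matched {len(matched.case_ids)} cases to {len(matched.control_ids)} "
          f"controls (ratio cap {args.ratio}, caliper {args.caliper}); "
          f"{len(matched.unmatched_case_ids)} cases unmatched")
    shrunk = (balance["smd_post"] < balance["smd_pre"]).sum()
    print(f"standardized differences shrank for {shrunk}/{len(balance)} covariates")
    print(balance[["covariate", "smd_pre", "smd_post"]].to_string(index=False))
    print(f"pairs -> {args.out}; balance -> {args.balance}")


if __name__ == "__main__":
    main()
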