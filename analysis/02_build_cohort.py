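#!/usr/bin/env python
"""Apply the study inclusion/exclusion rules to the claims tables: index
date in the accrual window, age 18-63, clean 183-day washout, depression
diagnosis within +/-30 days of index, a compliant second fill, continuous
enrollment, and the diagnosis/drug/procedure exclusion screens.

Writes the eligible cohort and a disposition count per failure reason.
"""

import argparse
import json
from pathlib import Path

from trdclaims import build_cohort, read_bundle


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--disposition", type=Path, default=Path("results/disposition.json"))
    args = ap.parse_args()

    bundle = read_bundle(args.data)
    cohort, disposition = build_cohort(
        bundle.patients, bundle.pharmacy_claims, bundle.medical_claims,
        bundle.enrollment, windows=bundle.config.study_window)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(args.out, index=False)
    args.disposition.write_text(json.dumps(disposition, indent=2, sort_keys=True))

    print(f"{disposition['eligible']} of {len(bundle.patients)} patients eligible")
    for reason, count in sorted(disposition.items()):
        if reason != "eligible" and count:
            print(f"  {reason}: {count}")
    print(f"cohort -> {args.out}; disposition -> {args.disposition}")


if __name__ == "__main__":
    main()
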