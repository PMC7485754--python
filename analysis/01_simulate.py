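#!/usr/bin/env python
"""Generate the synthetic claims bundle that stands in for the proprietary
commercial-claims extract: scripted TRD / non-TRD drug trajectories with
known prevalence and injected cost/utilization effects.

Writes patients, pharmacy_claims, medical_claims, enrollment and
ground_truth tables plus a manifest under --out.
"""

import argparse
from pathlib import Path

from trdclaims import SimulationConfig, generate_claims, write_bundle


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=5000, help="number of patients")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--trd-fraction", type=float, default=0.13)
    ap.add_argument("--cost-ratio", type=float, default=1.4)
    ap.add_argument("--utilization-ratio", type=float, default=1.35)
    ap.add_argument("--format", choices=("csv", "parquet"), default="csv")
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    config = SimulationConfig(
        n_patients=args.n, trd_trajectory_fraction=args.trd_fraction,
        cost_effect_ratio=args.cost_ratio,
        utilization_effect_ratio=args.utilization_ratio, seed=args.seed)
    bundle = generate_claims(config)
    manifest = write_bundle(bundle, args.out, fmt=args.format)

    gt = bundle.ground_truth
    print(f"wrote {args.out} (config hash {manifest['config_hash']})")
    for name, info in manifest["files"].items():
        print(f"  {name}: {info['rows']} rows")
    print(f"scripted TRD-trajectory prevalence: {gt['is_trd'].mean():.3f} "
          f"(target {args.trd_fraction})")
    print(f"trajectory mix: {gt['trajectory'].value_counts().to_dict()}")
    print(f"injected effects: cost x{args.cost_ratio}, visits x{args.utilization_ratio}, "
          f"ED OR {config.ed_effect_or}, hospitalization OR {config.hosp_effect_or}")


if __name__ == "__main__":
    main()
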