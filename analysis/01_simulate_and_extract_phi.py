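#!/usr/bin/env python
"""Simulate the synthetic cohort and extract PHI connectivity features.

Generates the default 88-subject cohort (AD 36 / FTD 23 / HC 29; 19
channels, 60 s at 500 Hz) with planted coupling ordered FTD > HC > AD
across the 13 analysis pairs, computes PHI on each subject's first
epoch, and writes per-subject PHI values, demographics, and the
per-pair group-mean summary.

Recordings are regenerated deterministically from the seed, so only the
small derived tables are persisted.
"""

import argparse
from pathlib import Path

import pandas as pd

from phieeg.pipeline import compute_cohort_phi, demographics_from_recordings, phi_results_to_frame
from phieeg.synthetic_data import default_cohort_spec, generate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

print(f"simulating cohort (seed {args.seed}) ...")
cohort = generate_cohort(default_cohort_spec(seed=args.seed))
demo = demographics_from_recordings(cohort)
demo.to_csv(args.out / "demographics.csv", index=False)

phi_results = compute_cohort_phi(cohort)
phi_df = phi_results_to_frame(phi_results)
phi_df.to_csv(args.out / "phi_values.csv", index=False)

merged = phi_df.merge(demo[["subject_id", "group"]].reset_index(drop=True), on="subject_id")
summary = (
    merged.pivot_table(index="pair", columns="group", values="phi", aggfunc=["mean", "std"])
    .round(3)
)
summary.to_csv(args.out / "phi_group_summary.csv")
print("\nGroup-mean PHI (bits) per electrode pair:")
print(summary["mean"].to_string())
print(
    "\nPlanted coupling is pair-specific: frontal pairs separate the dementias "
    f"from HC, temporal-parietal pairs separate AD from FTD; tables in {args.out}/"
)
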