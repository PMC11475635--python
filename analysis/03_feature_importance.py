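#!/usr/bin/env python
"""Permutation feature importance for each pairwise contrast.

For every contrast, permutes each of the 15 features 50 times, re-runs
the full LOOCV evaluation each time, and reports the mean and SD
decrease in accuracy; prints the top five features per contrast.
"""

import argparse
from pathlib import Path

import pandas as pd

from phieeg.eeg_io import load_demographics
from phieeg.features import build_feature_table
from phieeg.importance import permutation_importance, rank_features
from phieeg.pipeline import phi_frame_to_results

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--iterations", type=int, default=50)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

phi_results = phi_frame_to_results(pd.read_csv(args.out / "phi_values.csv"))
demo = load_demographics(args.out / "demographics.csv")

for contrast in [("AD", "HC"), ("FTD", "HC"), ("AD", "FTD")]:
    name = f"{contrast[0]}-{contrast[1]}"
    sids = demo.index[demo["group"].isin(contrast)]
    table = build_feature_table({s: phi_results[s] for s in sids}, demo)
    report = permutation_importance(
        table, positive_class=contrast[0], n_iterations=args.iterations, seed=args.seed
    )
    ranked = rank_features(report)
    df = pd.DataFrame(
        {
            "feature": report.feature_names,
            "mean_decrease": report.mean_decrease,
            "sd_decrease": report.sd_decrease,
        }
    )
    df["rank"] = [ranked.index(f) + 1 for f in report.feature_names]
    df = df.sort_values("rank")
    path = args.out / f"importance_{name}.csv"
    df.round(4).to_csv(path, index=False)
    print(f"\n{name} (baseline accuracy {report.baseline_accuracy:.3f}), top five features:")
    print(df.head(5).to_string(index=False))
    print(f"wrote {path}")
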