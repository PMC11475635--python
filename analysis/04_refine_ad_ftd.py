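#!/usr/bin/env python
"""Refine the AD-FTD feature set to the top 8 features and re-classify.

Reads the AD-FTD importance ranking from 03_feature_importance.py,
keeps the eight highest-ranked features, re-runs the LOOCV
classification on the reduced table, and appends the result to the
classification metrics table.
"""

import argparse
from pathlib import Path

import pandas as pd

from phieeg.classification import evaluate_contrast
from phieeg.eeg_io import load_demographics
from phieeg.features import build_feature_table
from phieeg.pipeline import phi_frame_to_results

parser = argparse.ArgumentParser()
parser.add_argument("--k", type=int, default=8)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

importance = pd.read_csv(args.out / "importance_AD-FTD.csv").sort_values("rank")
refined = importance["feature"].head(args.k).tolist()
print(f"top {args.k} AD-FTD features: {refined}")

phi_results = phi_frame_to_results(pd.read_csv(args.out / "phi_values.csv"))
demo = load_demographics(args.out / "demographics.csv")
sids = demo.index[demo["group"].isin(["AD", "FTD"])]
table = build_feature_table({s: phi_results[s] for s in sids}, demo, feature_subset=refined)
run, cm, rep = evaluate_contrast(table, ("AD", "FTD"))
print(f"AD-FTD with {args.k} features: accuracy {rep.accuracy:.3f} over {run.fold_count} folds")

metrics_path = args.out / "classification_metrics.csv"
metrics = pd.read_csv(metrics_path)
metrics = pd.concat(
    [
        metrics,
        pd.DataFrame(
            [
                {
                    "contrast": "AD-FTD", "n_features": args.k, "n_subjects": run.fold_count,
                    "accuracy": rep.accuracy, "f1": rep.f1, "precision": rep.precision,
                    "recall": rep.recall, "specificity": rep.specificity,
                }
            ]
        ).round(4),
    ],
    ignore_index=True,
)
metrics.to_csv(metrics_path, index=False)
print(f"appended refined row to {metrics_path}")
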