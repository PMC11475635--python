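#!/usr/bin/env python
"""Classify the three pairwise group contrasts with the sigmoid-kernel SVM.

Builds the 15-column feature table (13 PHI pairs + scaled age + sex)
from the tables written by 01_simulate_and_extract_phi.py, runs
leave-one-out cross-validation for AD-HC, FTD-HC and AD-FTD, and writes
support-weighted metrics per contrast.
"""

import argparse
from pathlib import Path

import pandas as pd

from phieeg.classification import evaluate_contrast
from phieeg.eeg_io import load_demographics
from phieeg.features import build_feature_table
from phieeg.pipeline import phi_frame_to_results

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

phi_results = phi_frame_to_results(pd.read_csv(args.out / "phi_values.csv"))
demo = load_demographics(args.out / "demographics.csv")

rows = []
for contrast in [("AD", "HC"), ("FTD", "HC"), ("AD", "FTD")]:
    # age scaling is fit per contrast, over the two groups being compared
    sids = demo.index[demo["group"].isin(contrast)]
    table = build_feature_table({s: phi_results[s] for s in sids}, demo)
    run, cm, rep = evaluate_contrast(table, contrast)
    rows.append(
        {
            "contrast": f"{contrast[0]}-{contrast[1]}", "n_features": 15,
            "n_subjects": run.fold_count, "accuracy": rep.accuracy, "f1": rep.f1,
            "precision": rep.precision, "recall": rep.recall, "specificity": rep.specificity,
        }
    )
    print(f"{contrast[0]}-{contrast[1]}: accuracy {rep.accuracy:.3f} over {run.fold_count} LOOCV folds")

out = args.out / "classification_metrics.csv"
pd.DataFrame(rows).round(4).to_csv(out, index=False)
print(f"\nwrote {out}")
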