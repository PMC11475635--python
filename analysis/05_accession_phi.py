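#!/usr/bin/env python
"""Run the PHI pipeline on the real clinical accession (if available locally).

Expects a local copy of OpenNeuro ds004504 v1.0.6 (derivatives: EEGLAB
``.set`` files, 19 channels at 500 Hz) and its participants table.  For
each subject, loads the preprocessed recording, takes the first 60-s
epoch, computes PHI over the 13 analysis pairs, and writes per-subject
values plus the per-pair group-mean summary for comparison with the
published descriptive statistics.

Usage:
    python analysis/05_accession_phi.py --data <ds004504-root> --out results/accession
"""

import argparse
from pathlib import Path

import pandas as pd

from phieeg.eeg_io import load_recording
from phieeg.pipeline import compute_cohort_phi, phi_results_to_frame

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, required=True, help="root of the BIDS dataset")
parser.add_argument("--out", type=Path, default=Path("results/accession"))
args = parser.parse_args()

participants = pd.read_csv(args.data / "participants.tsv", sep="\t")
group_map = {"A": "AD", "F": "FTD", "C": "HC"}

recordings = []
groups = {}
for row in participants.itertuples(index=False):
    sid = row.participant_id
    groups[sid] = group_map.get(str(row.Group), str(row.Group))
    set_files = sorted(args.data.glob(f"derivatives/*/{sid}/**/*.set")) or sorted(
        args.data.glob(f"{sid}/**/*.set")
    )
    if not set_files:
        print(f"warning: no .set file for {sid}, skipping")
        continue
    recordings.append(load_recording(set_files[0], format="eeglab_set", subject_id=sid))

if not recordings:
    raise SystemExit(f"no recordings found under {args.data}")

print(f"loaded {len(recordings)} recordings; computing PHI on first 60-s epochs ...")
phi_df = phi_results_to_frame(compute_cohort_phi(recordings))
phi_df["group"] = phi_df["subject_id"].map(groups)

args.out.mkdir(parents=True, exist_ok=True)
phi_df.to_csv(args.out / "phi_values.csv", index=False)
summary = phi_df.pivot_table(index="pair", columns="group", values="phi", aggfunc=["mean", "std"]).round(2)
summary.to_csv(args.out / "phi_group_summary.csv")
print(summary.to_string())
print(f"wrote {args.out}/phi_values.csv and phi_group_summary.csv")
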