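"""End-to-end helpers chaining epoching, PHI extraction and feature assembly."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .eeg_io import EEGRecording, ElectrodePair, first_epoch, load_recording
from .features import FeatureTable, build_feature_table
from .phi_core import DEFAULT_BIN_WIDTH, DEFAULT_PAIRS, PhiResult, phi_matrix


def compute_cohort_phi(
    recordings: list[EEGRecording],
    pairs: list[ElectrodePair] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    epoch_seconds: float = 60.0,
) -> dict[str, list[PhiResult]]:
    """PHI per pair for every recording, on its first epoch."""
    if pairs is None:
        pairs = DEFAULT_PAIRS
    out: dict[str, list[PhiResult]] = {}
    for rec in recordings:
        epoch = first_epoch(rec, duration=epoch_seconds)
        out[rec.subject_id] = phi_matrix(epoch, pairs, bin_width=bin_width)
    return out


def phi_results_to_frame(phi_results: dict[str, list[PhiResult]]) -> pd.DataFrame:
    """Long-format table: subject_id, pair, mi_ab, mi_ba, phi."""
    rows = [
        {"subject_id": sid, "pair": r.pair.name, "mi_ab": r.mi_ab, "mi_ba": r.mi_ba, "phi": r.phi}
        for sid, results in phi_results.items()
        for r in results
    ]
    return pd.DataFrame(rows)


def phi_frame_to_results(df: pd.DataFrame) -> dict[str, list[PhiResult]]:
    """Inverse of :func:`phi_results_to_frame`."""
    out: dict[str, list[PhiResult]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            PhiResult(
                pair=ElectrodePair.parse(row.pair),
                mi_ab=float(row.mi_ab),
                mi_ba=float(row.mi_ba),
                phi=float(row.phi),
            )
        )
    return out


def demographics_from_recordings(recordings: list[EEGRecording]) -> pd.DataFrame:
    """Demographics frame (indexed by subject_id) from recording metadata."""
    rows = [
        {"subject_id": rec.subject_id, "group": rec.group, "age": rec.age, "sex": rec.sex}
        for rec in recordings
    ]
    return pd.DataFrame(rows).set_index("subject_id", drop=False)


def load_cohort(directory: str | Path, format: str = "plain_matrix") -> list[EEGRecording]:
    """Load every recording file in a directory (sorted by name)."""
    directory = Path(directory)
    suffix = ".csv" if format == "plain_matrix" else ".set"
    paths = sorted(p for p in directory.glob(f"*{suffix}") if p.stem != "demographics")
    if not paths:
        raise FileNotFoundError(f"no {suffix} recordings found in {directory}")
    return [load_recording(p, format=format) for p in paths]


def feature_table_from_cohort(
    recordings: list[EEGRecording],
    pairs: list[ElectrodePair] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    epoch_seconds: float = 60.0,
    feature_subset: list[str] | None = None,
) -> FeatureTable:
    """Recordings → first epoch → PHI per pair → feature table."""
    phi_results = compute_cohort_phi(recordings, pairs, bin_width, epoch_seconds)
    demo = demographics_from_recordings(recordings)
    return build_feature_table(phi_results, demo, feature_subset=feature_subset)
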