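"""Per-subject feature assembly: PHI values per pair, scaled age, sex.

The canonical feature layout is the 13 analysis pairs in their standard
order, then ``age_scaled`` (min-max scaled to [0, 1] over the subjects
included in the table), then ``sex`` (male = 1, female = 0).  Age
scaling is fit on the full table before cross-validation by default,
replicating the reference procedure; pass
``scale_age_within_training_folds=True`` to the classifier for the
leakage-free variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phi_core import DEFAULT_PAIRS, PhiResult

AGE_FEATURE = "age_scaled"
SEX_FEATURE = "sex"

#: Canonical feature order: the 13 pairs, then demographics.
DEFAULT_FEATURES = [p.name for p in DEFAULT_PAIRS] + [AGE_FEATURE, SEX_FEATURE]

#: The refined 8-pair feature set for the AD–FTD contrast.
REFINED_8_FEATURES = ["T6-P4", "T5-P3", "T3-P3", "T3-T5", "T4-P4", "O1-O2", "T4-T6", "Fp2-T4"]


def scale_age(ages: np.ndarray) -> np.ndarray:
    """Min-max scale ages to [0, 1]: (a − min) / (max − min).

    A degenerate input (all ages equal, or a single subject) maps to all
    zeros with a warning.
    """
    a = np.asarray(ages, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("ages must be a non-empty 1-D array")
    if not np.all(np.isfinite(a)):
        raise ValueError("ages must be finite")
    lo, hi = a.min(), a.max()
    if a.size < 2 or hi == lo:
        warnings.warn("degenerate age column (no spread); scaled ages set to 0", stacklevel=2)
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def encode_sex(sex: list[str] | np.ndarray) -> np.ndarray:
    """Encode sex as male = 1, female = 0 (strict: only those two labels)."""
    coding = {"male": 1.0, "female": 0.0}
    out = np.empty(len(sex), dtype=float)
    for i, s in enumerate(sex):
        if s not in coding:
            raise ValueError(f"unknown sex category {s!r}; expected 'male' or 'female'")
        out[i] = coding[s]
    return out


@dataclass
class FeatureTable:
    """Subjects × features matrix with group labels.

    ``values[i, j]`` is feature ``feature_names[j]`` for subject
    ``subject_ids[i]``, whose group is ``labels[i]``.
    """

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids, labels and value rows must agree in length")
        if len(self.feature_names) != k:
            raise ValueError("feature_names must match value columns")
        if len(set(self.feature_names)) != k:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def subset_groups(self, groups: list[str]) -> "FeatureTable":
        """Rows whose label is in ``groups``, original order preserved."""
        keep = [i for i, g in enumerate(self.labels) if g in groups]
        if not keep:
            raise ValueError(f"no subjects with group in {groups}")
        return FeatureTable(
            subject_ids=[self.subject_ids[i] for i in keep],
            feature_names=list(self.feature_names),
            values=self.values[keep],
            labels=[self.labels[i] for i in keep],
        )

    def select_features(self, names: list[str]) -> "FeatureTable":
        missing = [nm for nm in names if nm not in self.feature_names]
        if missing:
            raise KeyError(f"feature(s) {missing} not in table")
        idx = [self.feature_names.index(nm) for nm in names]
        return FeatureTable(
            subject_ids=list(self.subject_ids),
            feature_names=list(names),
            values=self.values[:, idx],
            labels=list(self.labels),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "group", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, dtype={"subject_id": str})
        feature_cols = [c for c in df.columns if c not in ("subject_id", "group")]
        return cls(
            subject_ids=df["subject_id"].tolist(),
            feature_names=feature_cols,
            values=df[feature_cols].to_numpy(dtype=float),
            labels=df["group"].tolist(),
        )


def build_feature_table(
    phi_results: dict[str, list[PhiResult]],
    demographics: pd.DataFrame,
    feature_subset: list[str] | None = None,
) -> FeatureTable:
    """Assemble the subjects × features matrix.

    Parameters
    ----------
    phi_results
        subject_id → list of PhiResult (one per pair).
    demographics
        Indexed by subject_id with columns group, age, sex; only
        subjects present in ``phi_results`` are included.
    feature_subset
        Feature names and order for the output; defaults to the 13 pairs
        then age_scaled then sex.  Age scaling is computed over exactly
        the subjects in the table.
    """
    if feature_subset is None:
        feature_subset = list(DEFAULT_FEATURES)
    subject_ids = list(phi_results)
    missing_demo = [s for s in subject_ids if s not in demographics.index]
    if missing_demo:
        raise ValueError(f"demographics missing for subject(s) {missing_demo}")

    phi_by_subject = {}
    for sid, results in phi_results.items():
        phi_by_subject[sid] = {r.pair.name: r.phi for r in results}

    pair_features = [f for f in feature_subset if f not in (AGE_FEATURE, SEX_FEATURE)]
    for sid in subject_ids:
        absent = [f for f in pair_features if f not in phi_by_subject[sid]]
        if absent:
            raise ValueError(f"subject {sid!r} is missing PHI value(s) for pair(s) {absent}")

    columns: dict[str, np.ndarray] = {
        f: np.array([phi_by_subject[sid][f] for sid in subject_ids]) for f in pair_features
    }
    if AGE_FEATURE in feature_subset:
        ages = demographics.loc[subject_ids, "age"].to_numpy(dtype=float)
        columns[AGE_FEATURE] = scale_age(ages)
    if SEX_FEATURE in feature_subset:
        columns[SEX_FEATURE] = encode_sex(demographics.loc[subject_ids, "sex"].tolist())

    values = np.column_stack([columns[f] for f in feature_subset])
    labels = demographics.loc[subject_ids, "group"].tolist()
    return FeatureTable(
        subject_ids=subject_ids,
        feature_names=list(feature_subset),
        values=values,
        labels=labels,
    )
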