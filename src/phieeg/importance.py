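"""Permutation feature importance over the LOOCV pipeline, and refinement.

Importance of a feature is the decrease in leave-one-out accuracy when
that feature's column is shuffled across subjects, relative to the
intact-table baseline, averaged over permutation iterations (default
50).  Permutation happens on the whole table before the full LOOCV
re-evaluation.  Features are ranked by descending mean decrease, ties
broken by the table's column order; refinement keeps the top k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classification import SvmConfig, loocv_svm
from .features import FeatureTable

DEFAULT_ITERATIONS = 50


@dataclass
class ImportanceReport:
    """Mean/SD accuracy decrease per feature, in table column order."""

    feature_names: list[str]
    mean_decrease: np.ndarray
    sd_decrease: np.ndarray
    baseline_accuracy: float
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        self.mean_decrease = np.asarray(self.mean_decrease, dtype=float)
        self.sd_decrease = np.asarray(self.sd_decrease, dtype=float)
        k = len(self.feature_names)
        if self.mean_decrease.shape != (k,) or self.sd_decrease.shape != (k,):
            raise ValueError("one (mean, sd) pair per feature required")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def permutation_importance(
    table: FeatureTable,
    positive_class: str,
    config: SvmConfig | None = None,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation importance of every feature under LOOCV.

    For each feature and iteration, the feature column is shuffled
    across subjects with an independent draw from the seeded generator,
    the full leave-one-out evaluation is re-run, and the decrease
    baseline − permuted accuracy is recorded.  Deterministic given
    ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if table.n_subjects == 0 or not table.feature_names:
        raise ValueError("feature table must be non-empty")
    if config is None:
        config = SvmConfig()

    baseline = loocv_svm(table, positive_class, config).accuracy
    rng = np.random.default_rng(seed)
    n, k = table.values.shape
    decreases = np.empty((k, n_iterations))
    for j in range(k):
        for it in range(n_iterations):
            perm = rng.permutation(n)
            shuffled = table.values.copy()
            shuffled[:, j] = shuffled[perm, j]
            permuted_table = FeatureTable(
                subject_ids=list(table.subject_ids),
                feature_names=list(table.feature_names),
                values=shuffled,
                labels=list(table.labels),
            )
            decreases[j, it] = baseline - loocv_svm(permuted_table, positive_class, config).accuracy

    return ImportanceReport(
        feature_names=list(table.feature_names),
        mean_decrease=decreases.mean(axis=1),
        sd_decrease=decreases.std(axis=1, ddof=0),
        baseline_accuracy=baseline,
        n_iterations=n_iterations,
        seed=seed,
    )


def rank_features(report: ImportanceReport) -> list[str]:
    """Features by descending mean decrease; ties keep table column order."""
    order = sorted(
        range(len(report.feature_names)),
        key=lambda j: (-report.mean_decrease[j], j),
    )
    return [report.feature_names[j] for j in order]


def refine_feature_set(report: ImportanceReport, k: int) -> list[str]:
    """The top-k ranked features (the refinement step of the pipeline)."""
    if not 1 <= k <= len(report.feature_names):
        raise ValueError(
            f"k must lie in [1, {len(report.feature_names)}], got {k}"
        )
    return rank_features(report)[:k]
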