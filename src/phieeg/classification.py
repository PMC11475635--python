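"""Sigmoid-kernel SVM under leave-one-out cross-validation, with
confusion-matrix metrics.

Each pairwise group contrast (AD–HC, FTD–HC, AD–FTD) is a binary
classification: for n subjects, n models are fit, each on n−1 subjects,
and the held-out subject is predicted.  Metrics derive from the pooled
confusion matrix.  Two averaging modes exist: ``positive_class`` applies
the textbook formulas with respect to the declared positive group, and
``weighted`` (the default) averages per-class precision / recall / F1 /
specificity weighted by class support — in which case weighted recall
equals accuracy identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .features import AGE_FEATURE, FeatureTable


@dataclass(frozen=True)
class SvmConfig:
    """SVM hyperparameters; defaults are the reference configuration.

    ``gamma='scale'`` sets the kernel coefficient to
    1 / (n_features · Var(X)).
    """

    kernel: str = "sigmoid"
    C: float = 1.0
    gamma: str | float = "scale"
    coef0: float = 0.0

    def make_estimator(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma, coef0=self.coef0)


@dataclass
class LoocvRun:
    """Per-subject leave-one-out predictions for one contrast."""

    subject_ids: list[str]
    true_labels: list[str]
    predictions: list[str]
    config: SvmConfig

    def __post_init__(self) -> None:
        if not (len(self.subject_ids) == len(self.true_labels) == len(self.predictions)):
            raise ValueError("one prediction and one true label per subject required")

    @property
    def fold_count(self) -> int:
        return len(self.subject_ids)

    @property
    def accuracy(self) -> float:
        hits = sum(p == t for p, t in zip(self.predictions, self.true_labels))
        return hits / self.fold_count


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with respect to ``positive_class``."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions viewed with the other class as positive."""
        return ConfusionMatrix(
            tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp,
            positive_class=f"not-{self.positive_class}",
        )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    averaging: str


def loocv_svm(
    table: FeatureTable,
    positive_class: str,
    config: SvmConfig | None = None,
    scale_age_within_training_folds: bool = False,
) -> LoocvRun:
    """Leave-one-out cross-validation of the sigmoid-kernel SVM.

    Exactly two groups must be present.  The fit is deterministic: libsvm
    on a fixed binary problem involves no randomness, so repeated runs on
    identical inputs yield identical predictions.

    ``scale_age_within_training_folds`` refits the age min-max scaling on
    each training fold (min-max is affine-invariant, so rescaling the
    already-scaled column within the fold is exact); the default keeps
    the whole-table scaling of the reference procedure.
    """
    if config is None:
        config = SvmConfig()
    classes = sorted(set(table.labels))
    if len(classes) != 2:
        raise ValueError(f"LOOCV contrast requires exactly two groups, found {classes}")
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not among {classes}")
    counts = {c: table.labels.count(c) for c in classes}
    thin = [c for c, k in counts.items() if k < 2]
    if thin:
        raise ValueError(f"group(s) {thin} have fewer than 2 subjects; folds would be degenerate")

    X = table.values
    y = np.asarray(table.labels)
    n = table.n_subjects
    age_col = table.feature_names.index(AGE_FEATURE) if AGE_FEATURE in table.feature_names else None

    predictions: list[str] = []
    for i in range(n):
        train = np.arange(n) != i
        X_train, X_test = X[train].copy(), X[i:i + 1].copy()
        if scale_age_within_training_folds and age_col is not None:
            lo, hi = X_train[:, age_col].min(), X_train[:, age_col].max()
            if hi > lo:
                X_train[:, age_col] = (X_train[:, age_col] - lo) / (hi - lo)
                X_test[:, age_col] = (X_test[:, age_col] - lo) / (hi - lo)
            else:
                X_train[:, age_col] = 0.0
                X_test[:, age_col] = 0.0
        clf = config.make_estimator()
        clf.fit(X_train, y[train])
        predictions.append(str(clf.predict(X_test)[0]))

    return LoocvRun(
        subject_ids=list(table.subject_ids),
        true_labels=list(table.labels),
        predictions=predictions,
        config=config,
    )


def confusion(run: LoocvRun, positive_class: str) -> ConfusionMatrix:
    """Tally LOOCV predictions against truth for the declared positive class."""
    tp = fp = tn = fn = 0
    for truth, pred in zip(run.true_labels, run.predictions):
        if truth == positive_class:
            if pred == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if pred == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn, positive_class=positive_class)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def _positive_class_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    specificity = _safe_div(cm.tn, cm.tn + cm.fp, "specificity")
    return precision, recall, f1, specificity


def metrics(cm: ConfusionMatrix, averaging: str = "weighted") -> MetricsReport:
    """Accuracy, precision, recall, F1 and specificity from a confusion matrix.

    ``positive_class`` mode reports the raw formulas for the declared
    positive group; ``weighted`` mode averages both classes' metrics by
    class support (so recall coincides with accuracy).
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.n
    if averaging == "positive_class":
        precision, recall, f1, specificity = _positive_class_metrics(cm)
    elif averaging == "weighted":
        pos = _positive_class_metrics(cm)
        neg = _positive_class_metrics(cm.swapped())
        w_pos = (cm.tp + cm.fn) / cm.n
        w_neg = (cm.tn + cm.fp) / cm.n
        precision, recall, f1, specificity = (
            w_pos * p + w_neg * q for p, q in zip(pos, neg)
        )
    else:
        raise ValueError(f"unknown averaging mode {averaging!r}")
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall,
        f1=f1, specificity=specificity, averaging=averaging,
    )


def evaluate_contrast(
    table: FeatureTable,
    groups: tuple[str, str],
    config: SvmConfig | None = None,
    averaging: str = "weighted",
) -> tuple[LoocvRun, ConfusionMatrix, MetricsReport]:
    """Convenience wrapper: subset to two groups, LOOCV, confusion, metrics.

    The first-named group of the contrast is the positive class.
    """
    sub = table.subset_groups(list(groups))
    run = loocv_svm(sub, positive_class=groups[0], config=config)
    cm = confusion(run, positive_class=groups[0])
    return run, cm, metrics(cm, averaging=averaging)
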