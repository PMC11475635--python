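"""LOOCV SVM behaviour and confusion-matrix metric arithmetic."""

import numpy as np
import pytest
from scipy import stats

from phieeg.classification import (
    ConfusionMatrix,
    SvmConfig,
    confusion,
    loocv_svm,
    metrics,
)
from phieeg.features import FeatureTable


def make_table(X, labels):
    return FeatureTable(
        subject_ids=[f"s{i}" for i in range(len(labels))],
        feature_names=[f"f{j}" for j in range(X.shape[1])],
        values=X,
        labels=list(labels),
    )


def separable_table(n_per_class=10, n_features=3, gap_sd=5.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per_class, n_features))
    b = rng.normal(gap_sd, 1.0, (n_per_class, n_features))
    return make_table(np.vstack([a, b]), ["AD"] * n_per_class + ["HC"] * n_per_class)


class TestLoocv:
    def test_one_prediction_per_subject(self):
        run = loocv_svm(separable_table(), "AD")
        assert run.fold_count == 20
        assert len(run.predictions) == 20

    def test_wide_margin_classes_learned_perfectly(self):
        """Class-conditional means 5 SD apart: LOOCV accuracy must be 1."""
        run = loocv_svm(separable_table(), "AD")
        assert run.accuracy == 1.0

    def test_deterministic(self):
        table = separable_table(gap_sd=1.0)
        r1 = loocv_svm(table, "AD")
        r2 = loocv_svm(table, "AD")
        assert r1.predictions == r2.predictions

    def test_label_independent_features_score_near_chance(self):
        """Balanced labels assigned independently of the features: accuracy
        stays inside the binomial 95% band around 0.5."""
        rng = np.random.default_rng(123)
        X = rng.normal(0, 1, (40, 5))
        table = make_table(X, ["AD"] * 20 + ["HC"] * 20)
        acc = loocv_svm(table, "AD").accuracy
        lo, hi = stats.binom.ppf([0.025, 0.975], 40, 0.5) / 40
        assert lo <= acc <= hi

    def test_rejects_more_than_two_classes(self):
        table = make_table(np.zeros((6, 2)), ["AD", "AD", "HC", "HC", "FTD", "FTD"])
        with pytest.raises(ValueError, match="two groups"):
            loocv_svm(table, "AD")

    def test_rejects_singleton_class(self):
        table = make_table(np.zeros((3, 2)), ["AD", "HC", "HC"])
        with pytest.raises(ValueError, match="fewer than 2"):
            loocv_svm(table, "AD")

    def test_fold_age_scaling_variant_runs(self):
        table = separable_table()
        table.feature_names[-1] = "age_scaled"
        run = loocv_svm(table, "AD", scale_age_within_training_folds=True)
        assert run.fold_count == 20


class TestConfusion:
    def test_perfect_predictions(self):
        run = loocv_svm(separable_table(), "AD")
        cm = confusion(run, "AD")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)

    def test_counts_sum_to_n(self):
        run = loocv_svm(separable_table(gap_sd=0.5, seed=3), "AD")
        cm = confusion(run, "AD")
        assert cm.n == run.fold_count

    def test_all_predicted_positive(self):
        from phieeg.classification import LoocvRun

        run = LoocvRun(["a", "b"], ["AD", "HC"], ["AD", "AD"], SvmConfig())
        cm = confusion(run, "AD")
        assert cm.fn == 0 and cm.tn == 0 and cm.tp == 1 and cm.fp == 1


class TestMetrics:
    def test_symmetric_confusion_gives_one_half_everywhere(self):
        cm = ConfusionMatrix(tp=1, fp=1, tn=1, fn=1, positive_class="AD")
        rep = metrics(cm, averaging="positive_class")
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == rep.specificity == 0.5

    def test_hand_computed_counts(self):
        cm = ConfusionMatrix(tp=9, fp=2, tn=8, fn=1, positive_class="AD")
        rep = metrics(cm, averaging="positive_class")
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision == pytest.approx(9 / 11)
        assert rep.recall == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(2 * (9 / 11) * 0.9 / (9 / 11 + 0.9))

    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=10, fp=0, tn=10, fn=0, positive_class="AD")
        for mode in ("positive_class", "weighted"):
            rep = metrics(cm, averaging=mode)
            assert rep.accuracy == rep.precision == rep.recall == rep.f1 == rep.specificity == 1.0

    def test_weighted_recall_equals_accuracy(self, rng):
        """Support-weighted recall coincides with accuracy for any counts."""
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if tp + fp + tn + fn == 0:
                continue
            cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn), "AD")
            rep = metrics(cm, averaging="weighted")
            assert rep.recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_weighted_matches_sklearn(self):
        """Cross-check weighted precision/recall/F1 against scikit-learn."""
        from sklearn.metrics import precision_recall_fscore_support

        y_true = ["AD"] * 10 + ["HC"] * 8
        y_pred = ["AD"] * 7 + ["HC"] * 3 + ["HC"] * 6 + ["AD"] * 2
        tp = sum(t == p == "AD" for t, p in zip(y_true, y_pred))
        fn = sum(t == "AD" and p == "HC" for t, p in zip(y_true, y_pred))
        tn = sum(t == p == "HC" for t, p in zip(y_true, y_pred))
        fp = sum(t == "HC" and p == "AD" for t, p in zip(y_true, y_pred))
        rep = metrics(ConfusionMatrix(tp, fp, tn, fn, "AD"), averaging="weighted")
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
        assert rep.precision == pytest.approx(p)
        assert rep.recall == pytest.approx(r)
        assert rep.f1 == pytest.approx(f1)

    def test_zero_denominator_warns_and_returns_zero(self):
        cm = ConfusionMatrix(tp=0, fp=0, tn=5, fn=5, positive_class="AD")
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = metrics(cm, averaging="positive_class")
        assert rep.precision == 0.0


class TestPermutationNull:
    def test_mean_accuracy_over_label_shufflings_is_chance(self):
        """Shuffling labels 20 times: mean LOOCV accuracy falls inside the
        binomial 99% band of chance performance."""
        rng = np.random.default_rng(2024)
        X = rng.normal(0, 1, (40, 5))
        labels = np.array(["AD"] * 20 + ["HC"] * 20)
        accs = []
        for _ in range(20):
            shuffled = labels[rng.permutation(40)]
            accs.append(loocv_svm(make_table(X, list(shuffled)), "AD").accuracy)
        mean_acc = np.mean(accs)
        # 99% band for the mean of 20 x 40 approximately-Bernoulli outcomes
        half_width = 2.576 * 0.5 / np.sqrt(20 * 40)
        assert abs(mean_acc - 0.5) < half_width + 0.05
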