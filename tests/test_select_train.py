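"""Feature selection, class weighting, subject splits, training, and
confusion-matrix arithmetic (checked against the reference confusion
matrices of the study design this package models)."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from drivewave.select_train import (
    MODEL_KINDS,
    FTestSelector,
    WeightedKNNClassifier,
    accuracy_from_confusion,
    class_weights,
    evaluate,
    feature_importance_ftest,
    make_classifier,
    split_by_subject,
    train_classifier,
)


def _blobs(rng, n_per=60, sep=6.0, k=3, d=5):
    X = np.vstack([
        rng.normal(i * sep, 1.0, (n_per, d)) for i in range(k)
    ])
    y = np.repeat([f"c{i}" for i in range(k)], n_per)
    return X, y


class TestFeatureImportance:
    def _table(self, rng, effect):
        n = 50
        labels = np.repeat(["a", "b"], n)
        strong = np.concatenate([rng.normal(0, 1, n), rng.normal(effect, 1, n)])
        weak = rng.normal(0, 1, 2 * n)
        return pd.DataFrame(
            dict(state=labels, strong=strong, weak=weak, const=1.0)
        )

    def test_indistinguishable_feature_not_selected(self, rng):
        table = self._table(rng, effect=0.0)
        imps = {fi.feature: fi for fi in feature_importance_ftest(table)}
        assert not imps["weak"].selected

    def test_separated_feature_selected(self, rng):
        table = self._table(rng, effect=10.0)
        imps = {fi.feature: fi for fi in feature_importance_ftest(table)}
        assert imps["strong"].selected
        assert imps["strong"].importance > 0.95

    def test_constant_feature_screened_not_scored(self, rng):
        table = self._table(rng, effect=1.0)
        names = [fi.feature for fi in feature_importance_ftest(table)]
        assert "const" not in names

    def test_selector_transform_keeps_selected_columns(self, rng):
        table = self._table(rng, effect=10.0)
        sel = FTestSelector().fit(table[["strong", "weak", "const"]],
                                  table["state"])
        out = sel.transform(table)
        assert "strong" in out.columns and "const" not in out.columns

    def test_state_cohort_importances_are_valid(self, small_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imps = feature_importance_ftest(small_table)
        assert all(0.0 <= fi.importance <= 1.0 for fi in imps)
        assert any(fi.selected for fi in imps)


class TestSubjectSplit:
    def test_partition_counts(self, small_table):
        tr, te = split_by_subject(small_table, ["S01", "S02", "S03"], ["S04"])
        assert len(tr) + len(te) == len(small_table)
        assert set(tr.subject).isdisjoint(set(te.subject))

    def test_overlapping_subjects_rejected(self, small_table):
        with pytest.raises(ValueError, match="both partitions"):
            split_by_subject(small_table, ["S01", "S02"], ["S02", "S04"])

    def test_empty_test_set_rejected(self, small_table):
        with pytest.raises(ValueError, match="non-empty"):
            split_by_subject(small_table, ["S01", "S02", "S03", "S04"], [])


class TestClassWeights:
    def test_balanced_classes_unit_weights(self):
        w = class_weights(np.repeat(["a", "b", "c"], 10))
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_study_epoch_counts(self):
        labels = np.repeat(
            ["rest", "city", "exp"], [51, 459, 306]
        )
        w = class_weights(labels)
        assert w["rest"] == pytest.approx(816 / (3 * 51), rel=1e-9)  # 5.33
        assert w["city"] == pytest.approx(0.5926, abs=0.001)
        assert w["exp"] == pytest.approx(0.8889, abs=0.001)
        assert w["rest"] > w["exp"] > w["city"]

    def test_single_class_flagged(self):
        with pytest.warns(UserWarning, match="single class"):
            w = class_weights(np.array(["a", "a"]))
        assert w == {"a": 1.0}


class TestTraining:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_separable_blobs_cv_accuracy(self, rng, kind):
        X, y = _blobs(rng)
        res = train_classifier(kind, X, y, cv_k=5, seed=0)
        assert res.cv_accuracy > 0.95

    @pytest.mark.parametrize("kind", ["knn", "svm_rbf", "tree_gain_ratio"])
    def test_permuted_labels_give_chance_accuracy(self, rng, kind):
        X, y = _blobs(rng, n_per=50)
        y = rng.permutation(y)
        res = train_classifier(kind, X, y, cv_k=5, seed=0)
        assert res.cv_accuracy == pytest.approx(1 / 3, abs=0.12)

    def test_determinism_across_runs(self, rng):
        X, y = _blobs(rng)
        r1 = train_classifier("svm_rbf", X, y, cv_k=5, seed=3)
        r2 = train_classifier("svm_rbf", X, y, cv_k=5, seed=3)
        assert r1.cv_scores == r2.cv_scores

    def test_fold_count_reduced_for_small_classes(self, rng):
        X, y = _blobs(rng, n_per=6)
        with pytest.warns(UserWarning, match="reduced folds"):
            res = train_classifier("knn", X, y, cv_k=10, seed=0)
        assert res.cv_k == 6

    def test_repeated_cv_is_stable(self, rng):
        X, y = _blobs(rng, sep=2.5)
        res = train_classifier("knn", X, y, cv_k=5, repeats=3, seed=0)
        per_rep = np.array(res.cv_scores).reshape(3, 5).mean(axis=1)
        assert np.ptp(per_rep) < 0.05

    def test_class_weighting_recovers_minority_class(self, rng):
        # overlapping minority class: weighting must raise its recall
        X = np.vstack([
            rng.normal(0.0, 1.0, (200, 3)),
            rng.normal(1.2, 1.0, (12, 3)),
        ])
        y = np.array(["maj"] * 200 + ["min"] * 12)
        w = class_weights(y)
        m_w = make_classifier("svm_rbf", w)
        m_u = make_classifier("svm_rbf", None)
        m_w.fit(X, y)
        m_u.fit(X, y)
        recall_w = np.mean(m_w.predict(X[y == "min"]) == "min")
        recall_u = np.mean(m_u.predict(X[y == "min"]) == "min")
        assert recall_w > recall_u

    def test_weighted_knn_tie_breaks_to_nearest(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["a", "b", "b"])
        knn = WeightedKNNClassifier(n_neighbors=3,
                                    class_weight={"a": 2.0, "b": 1.0})
        knn.fit(X, y)
        # votes tie (a: 2.0, b: 2.0) -> nearest neighbour decides
        assert knn.predict(np.array([[0.1]]))[0] == "a"
        assert knn.predict(np.array([[1.9]]))[0] == "b"


# Reference confusion matrices (actual rows: city, expressway, resting).
_T4 = {
    "knn_train": ([[234, 59, 2], [74, 191, 0], [2, 0, 31]],
                  [79.32, 72.08, 93.94], None),
    "discriminant_train": ([[214, 80, 1], [82, 182, 1], [2, 0, 31]],
                           [72.54, 68.68, 93.94], 72.01),
    "svm_train": ([[242, 53, 0], [72, 193, 0], [0, 0, 33]],
                  [82.03, 72.83, 100.0], 78.92),
    "c5_train": ([[285, 10, 0], [11, 254, 0], [0, 0, 33]],
                 [96.61, 95.85, 100.0], 96.46),
    "quest_train": ([[217, 76, 2], [108, 151, 6], [0, 0, 33]],
                    [73.56, 56.98, 100.0], None),
    "knn_test": ([[88, 50, 1], [36, 53, 0], [2, 0, 16]],
                 [63.31, 59.55, 88.89], None),
    "discriminant_test": ([[87, 50, 2], [29, 59, 1], [1, 1, 16]],
                          [62.59, 66.29, 88.89], None),
    "svm_test": ([[96, 42, 1], [33, 56, 0], [1, 0, 17]],
                 [69.06, 62.92, 94.44], 68.70),
    "c5_test": ([[82, 56, 1], [27, 61, 1], [1, 1, 16]],
                [58.99, 68.54, 88.89], 64.63),
    "quest_test": ([[88, 48, 3], [34, 53, 2], [0, 0, 18]],
                   [63.31, 59.55, 100.0], 64.63),
}


class TestConfusionArithmetic:
    @pytest.mark.parametrize("name", list(_T4))
    def test_reference_matrices_reproduce_printed_accuracies(self, name):
        matrix, per_class, overall = _T4[name]
        acc = accuracy_from_confusion(matrix)
        got = [round(100 * v, 2) for v in acc["per_class"]]
        assert got == [round(v, 2) for v in per_class]
        if overall is not None:
            assert round(100 * acc["overall"], 2) == overall

    def test_identity_matrix_is_perfect(self):
        acc = accuracy_from_confusion(np.eye(3) * 7)
        assert acc["overall"] == 1.0
        assert acc["per_class"] == [1.0, 1.0, 1.0]

    def test_training_matrices_sum_to_593_rows(self):
        for name, (m, _, _) in _T4.items():
            if name.endswith("train"):
                assert np.sum(m) == 593

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            accuracy_from_confusion([[1, 2], [3, -1]])
        with pytest.raises(ValueError):
            accuracy_from_confusion(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            accuracy_from_confusion(np.ones((2, 3)))


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        X, y = _blobs(rng, k=2, sep=10.0)
        model = make_classifier("svm_rbf").fit(X, y)
        rep = evaluate(model, X, y, "svm_rbf")
        assert rep.overall_accuracy == 1.0
        assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))
        assert rep.auc == 1.0 and rep.gini == 1.0

    def test_gini_is_twice_auc_minus_one(self, rng):
        X = rng.normal(0, 1, (120, 4))
        y = np.where(X[:, 0] + rng.normal(0, 1.5, 120) > 0, "p", "n")
        model = make_classifier("discriminant").fit(X, y)
        rep = evaluate(model, X, y, "discriminant")
        assert rep.gini == pytest.approx(2 * rep.auc - 1, abs=1e-12)

    def test_chance_scores_give_half_auc(self, rng):
        X = rng.normal(0, 1, (200, 4))
        y = np.array(["p", "n"] * 100)
        model = make_classifier("discriminant").fit(X, y)
        rep = evaluate(model, X, y, "discriminant")
        assert rep.auc == pytest.approx(0.5, abs=0.12)

    def test_permutation_importances_rank_informative_feature(self, rng):
        X = rng.normal(0, 1, (150, 3))
        y = np.where(X[:, 1] > 0, "p", "n")
        model = make_classifier("knn").fit(X, y)
        rep = evaluate(model, X, y, "knn",
                       feature_names=["a", "b", "c"], importances=True)
        assert max(rep.importances, key=rep.importances.get) == "b"

    def test_reference_accuracy_from_discriminant_training_matrix(self):
        # (214 + 182 + 31) / 593
        acc = accuracy_from_confusion(_T4["discriminant_train"][0])
        assert round(100 * acc["overall"], 2) == 72.01
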