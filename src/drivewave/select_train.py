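"""Feature selection, class weighting, model training and evaluation.

The modelling protocol: screen constant/missing features, score the rest
with a one-way ANOVA F-test (importance = 1 - p, selected when > 0.95),
split train/test by subject (12 training / 5 testing by default), weight
classes by inverse frequency to counter the resting-class minority, train
one of five classifier families with stratified 10-fold cross-validation,
and report confusion matrices, per-class and overall accuracy, and — for
binary tasks — ROC, AUC and the Gini coefficient (2*AUC - 1).

Model families: KNN (k=3, Euclidean, class-weighted votes), linear
discriminant analysis (equal priors under inverse-frequency weighting),
RBF-kernel SVM, a gain-ratio/pessimistically-pruned tree and an
ANOVA-split univariate tree (see `drivewave.trees`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.feature_selection import f_classif
from sklearn.inspection import permutation_importance
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .trees import GainRatioTreeClassifier, UnbiasedUnivariateTreeClassifier

__all__ = [
    "FeatureImportance",
    "FTestSelector",
    "feature_importance_ftest",
    "split_by_subject",
    "class_weights",
    "WeightedKNNClassifier",
    "make_classifier",
    "train_classifier",
    "evaluate",
    "accuracy_from_confusion",
    "ClassifierReport",
    "MODEL_KINDS",
]

MODEL_KINDS = ("knn", "discriminant", "svm_rbf", "tree_gain_ratio", "tree_univariate")

IMPORTANCE_THRESHOLD = 0.95


@dataclass(frozen=True)
class FeatureImportance:
    feature: str
    f_statistic: float
    p_value: float

    @property
    def importance(self) -> float:
        return 1.0 - self.p_value

    @property
    def selected(self) -> bool:
        return self.importance > IMPORTANCE_THRESHOLD


def feature_importance_ftest(
    table: pd.DataFrame, labels: np.ndarray | pd.Series | None = None,
    feature_cols: list[str] | None = None,
) -> list[FeatureImportance]:
    """Per-feature one-way ANOVA F across classes; importance = 1 - p.

    Constant and all-missing features are screened out (not scored).
    ``table`` may carry ``subject``/``state``/``epoch`` columns; ``labels``
    defaults to the ``state`` column.
    """
    if labels is None:
        labels = table["state"]
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    if feature_cols is None:
        feature_cols = [
            c for c in table.columns
            if c not in ("subject", "state", "epoch")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    out = []
    for col in feature_cols:
        v = table[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() == 0 or np.ptp(v[ok]) == 0:
            continue  # screened: constant or all-missing
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = f_classif(v[ok].reshape(-1, 1), labels[ok])
        out.append(FeatureImportance(col, float(F[0]), float(p[0])))
    return out


class FTestSelector(BaseEstimator):
    """Sklearn-style transformer keeping features with importance > 0.95."""

    def __init__(self, threshold: float = IMPORTANCE_THRESHOLD):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y) -> "FTestSelector":
        imps = feature_importance_ftest(X, y)
        self.importances_ = imps
        self.selected_features_ = [
            fi.feature for fi in imps if fi.importance > self.threshold
        ]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_features_")
        return X[self.selected_features_]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


def split_by_subject(
    table: pd.DataFrame,
    train_subjects: list[str],
    test_subjects: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition epochs by subject; no subject may appear in both sets."""
    train_set, test_set = set(train_subjects), set(test_subjects)
    overlap = train_set & test_set
    if overlap:
        raise ValueError(f"subjects in both partitions: {sorted(overlap)}")
    if not train_set or not test_set:
        raise ValueError("both partitions must be non-empty")
    all_subj = set(table["subject"])
    uncovered = all_subj - train_set - test_set
    if uncovered:
        raise ValueError(f"subjects in neither partition: {sorted(uncovered)}")
    return (
        table[table["subject"].isin(train_set)].copy(),
        table[table["subject"].isin(test_set)].copy(),
    )


def class_weights(labels: np.ndarray | pd.Series) -> dict:
    """Inverse-frequency class weights w_c = N / (K * n_c) (mean 1 per row)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) == 1:
        warnings.warn("single class: degenerate weighting")
        return {classes[0]: 1.0}
    N, K = len(labels), len(classes)
    return {c: N / (K * n) for c, n in zip(classes, counts)}


class WeightedKNNClassifier(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbours with class-weighted votes.

    Each neighbour votes with its class's weight; ties are broken by the
    nearest neighbour's class.  ``predict_proba`` returns normalized
    weighted votes.
    """

    def __init__(self, n_neighbors: int = 3, class_weight: dict | None = None):
        self.n_neighbors = n_neighbors
        self.class_weight = class_weight

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, self._y = np.unique(y, return_inverse=True)
        self._nn = NearestNeighbors(n_neighbors=self.n_neighbors).fit(X)
        cw = self.class_weight or {}
        self._w = np.array([cw.get(c, 1.0) for c in self.classes_])
        self.n_features_in_ = X.shape[1]
        return self

    def _votes(self, X):
        X = check_array(X)
        _, idx = self._nn.kneighbors(X)
        votes = np.zeros((len(X), len(self.classes_)))
        for k in range(self.n_neighbors):
            lab = self._y[idx[:, k]]
            votes[np.arange(len(X)), lab] += self._w[lab]
        return votes, idx

    def predict_proba(self, X):
        check_is_fitted(self, "_nn")
        votes, _ = self._votes(X)
        tot = votes.sum(axis=1, keepdims=True)
        return votes / tot

    def predict(self, X):
        check_is_fitted(self, "_nn")
        votes, idx = self._votes(X)
        best = np.argmax(votes, axis=1)
        # tie-break by nearest neighbour
        top = votes.max(axis=1, keepdims=True)
        tied = (np.abs(votes - top) < 1e-12).sum(axis=1) > 1
        best[tied] = self._y[idx[tied, 0]]
        return self.classes_[best]


def make_classifier(
    kind: str, class_weight: dict | None = None, seed: int = 0
) -> BaseEstimator:
    """Build one of the five model families (standardized where needed)."""
    if kind == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("knn", WeightedKNNClassifier(n_neighbors=3, class_weight=class_weight)),
        ])
    if kind == "discriminant":
        # inverse-frequency weighting == equal priors for LDA
        priors = None
        if class_weight is not None:
            k = len(class_weight)
            priors = np.full(k, 1.0 / k)
        return Pipeline([
            ("scale", StandardScaler()),
            ("lda", LinearDiscriminantAnalysis(priors=priors)),
        ])
    if kind == "svm_rbf":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(
                kernel="rbf", gamma="scale", class_weight=class_weight,
                random_state=seed,
            )),
        ])
    if kind == "tree_gain_ratio":
        return GainRatioTreeClassifier()
    if kind == "tree_univariate":
        return UnbiasedUnivariateTreeClassifier()
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def _fit_with_weights(model, X, y, class_weight):
    """Fit, passing per-sample weights to estimators that accept them."""
    if isinstance(model, (GainRatioTreeClassifier, UnbiasedUnivariateTreeClassifier)):
        sw = None
        if class_weight is not None:
            sw = np.array([class_weight[c] for c in y])
        model.fit(X, y, sample_weight=sw)
    else:
        model.fit(X, y)
    return model


@dataclass
class TrainResult:
    model: BaseEstimator
    kind: str
    cv_scores: list[float]
    cv_k: int
    seed: int

    @property
    def cv_accuracy(self) -> float:
        return float(np.mean(self.cv_scores))


def train_classifier(
    kind: str,
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    weights: dict | None = None,
    cv_k: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> TrainResult:
    """Stratified k-fold CV accuracy plus a final fit on all training rows.

    If the smallest class has fewer members than ``cv_k`` the fold count is
    reduced (with a warning).  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    k = min(cv_k, counts.min())
    if k < cv_k:
        warnings.warn(
            f"reduced folds from {cv_k} to {k}: smallest class has "
            f"{counts.min()} rows"
        )
    scores = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for tr, va in skf.split(X, y):
            m = clone(make_classifier(kind, weights, seed))
            _fit_with_weights(m, X[tr], y[tr], weights)
            scores.append(float(np.mean(m.predict(X[va]) == y[va])))
    final = _fit_with_weights(make_classifier(kind, weights, seed), X, y, weights)
    return TrainResult(final, kind, scores, k, seed)


class ConfusionAccuracy(dict):
    pass


def accuracy_from_confusion(matrix) -> dict:
    """Per-class and overall accuracy from an actual-by-predicted matrix.

    Overall = trace / total; per-class = diagonal / row sum (i.e. recall of
    the actual class).  Values are fractions.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (M < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = M.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    rowsum = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(rowsum > 0, np.diag(M) / rowsum, np.nan)
    return {
        "overall": float(np.trace(M) / total),
        "per_class": per_class.tolist(),
    }


@dataclass
class ClassifierReport:
    """Evaluation summary of one fitted model on one dataset."""

    kind: str
    classes: list
    confusion: np.ndarray  # rows = actual, cols = predicted
    per_class_accuracy: list[float]
    overall_accuracy: float
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)
    auc: float | None = None
    gini: float | None = None
    importances: dict[str, float] = field(default_factory=dict)
    cv_scores: list[float] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": self.per_class_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "auc": self.auc,
            "gini": self.gini,
            "importances": self.importances,
            "cv_scores": self.cv_scores,
            "seed": self.seed,
        }
        if self.roc is not None:
            d["roc"] = {
                "fpr": self.roc[0].tolist(), "tpr": self.roc[1].tolist()
            }
        return d


def _decision_scores(model, X) -> np.ndarray | None:
    """Binary decision scores for ROC (positive class = classes_[1])."""
    if hasattr(model, "decision_function"):
        try:
            s = model.decision_function(X)
            if s.ndim == 1:
                return s
        except Exception:
            pass
    if hasattr(model, "predict_proba"):
        p = model.predict_proba(X)
        if p.shape[1] == 2:
            return p[:, 1]
    return None


def evaluate(
    model,
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    kind: str = "",
    feature_names: list[str] | None = None,
    importances: bool = False,
    seed: int = 0,
) -> ClassifierReport:
    """Confusion matrix, accuracies and (binary) ROC/AUC/Gini on a test set.

    The Gini coefficient is 2*AUC - 1.  Predictor importances, when
    requested, use permutation importance (accuracy drop over 5 shuffles)
    for every model family alike.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    y = np.asarray(y)
    classes = list(getattr(model, "classes_", np.unique(y)))
    y_pred = model.predict(X)
    M = confusion_matrix(y, y_pred, labels=classes)
    acc = accuracy_from_confusion(M)
    roc = auc_val = gini = None
    if len(classes) == 2:
        scores = _decision_scores(model, X)
        if scores is not None:
            fpr, tpr, _ = roc_curve(y, scores, pos_label=classes[1])
            roc = (fpr, tpr)
            auc_val = float(_trapezoid_auc(fpr, tpr))
            gini = 2 * auc_val - 1
    imp = {}
    if importances:
        r = permutation_importance(
            model, X, y, n_repeats=5, random_state=seed, scoring="accuracy"
        )
        names = feature_names or [f"x{i}" for i in range(X.shape[1])]
        imp = {n: float(v) for n, v in zip(names, r.importances_mean)}
    return ClassifierReport(
        kind=kind, classes=classes, confusion=M,
        per_class_accuracy=acc["per_class"], overall_accuracy=acc["overall"],
        roc=roc, auc=auc_val, gini=gini, importances=imp, seed=seed,
    )
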