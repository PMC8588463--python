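"""Decision-tree classifiers in the style of two legacy algorithms.

`GainRatioTreeClassifier` follows the C4.5/C5.0 recipe: axis-aligned
binary splits chosen by *gain ratio* (information gain normalized by the
split's own entropy, which removes the bias toward many-valued
predictors), grown deep and then pruned bottom-up by pessimistic
(confidence-bound) error estimates.

`UnbiasedUnivariateTreeClassifier` follows the QUEST recipe: the split
*variable* is chosen first, by a per-feature one-way ANOVA F-test
(separating variable selection from split-point search removes selection
bias), and the split *point* is the midpoint between the two superclass
means (classes grouped into two superclasses by 2-means on their
per-class means).  Growth stops when no feature is significant.

Both are scikit-learn estimators (``fit``/``predict``/``predict_proba``,
``get_params``/``set_params``) and accept ``sample_weight``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["GainRatioTreeClassifier", "UnbiasedUnivariateTreeClassifier"]


@dataclass
class _Node:
    counts: np.ndarray  # weighted class counts at the node
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    n: float = 0.0  # weighted sample count

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def make_leaf(self) -> None:
        self.left = self.right = None
        self.feature = -1


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot <= 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _pessimistic_errors(n: float, e: float, z: float) -> float:
    """Upper confidence bound on the error count of a leaf (C4.5-style)."""
    if n <= 0:
        return 0.0
    f = e / n
    num = f + z**2 / (2 * n) + z * np.sqrt(f / n - f**2 / n + z**2 / (4 * n**2))
    return n * num / (1 + z**2 / n)


class _TreeBase(ClassifierMixin, BaseEstimator):
    def _more_tags(self):
        return {"requires_y": True}

    def fit(self, X, y, sample_weight=None):
        X, y = check_X_y(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        if sample_weight is None:
            sample_weight = np.ones(len(y))
        else:
            sample_weight = np.asarray(sample_weight, dtype=float)
        self.tree_ = self._grow(X, y_enc, sample_weight, depth=0)
        self._postprocess(X, y_enc, sample_weight)
        return self

    def _postprocess(self, X, y, w):  # pragma: no cover - default no-op
        pass

    def _grow(self, X, y, w, depth):
        raise NotImplementedError

    def _leaf_counts(self, y, w):
        counts = np.zeros(len(self.classes_))
        np.add.at(counts, y, w)
        return counts

    def _predict_counts(self, X):
        X = check_array(X)
        out = np.empty((len(X), len(self.classes_)))
        for i, x in enumerate(X):
            node = self.tree_
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.counts
        return out

    def predict_proba(self, X):
        check_is_fitted(self, "tree_")
        counts = self._predict_counts(X)
        tot = counts.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return counts / tot

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class GainRatioTreeClassifier(_TreeBase):
    """Binary-split tree with gain-ratio splitting and pessimistic pruning.

    Parameters
    ----------
    max_depth : maximum tree depth (None = unlimited).
    min_samples_split : minimum (weighted) samples to attempt a split.
    min_samples_leaf : minimum (weighted) samples in a child.
    pruning_z : z-score of the pessimistic error bound (0.674 corresponds
        to the customary 25% confidence level); None disables pruning.
    """

    def __init__(
        self,
        max_depth: int | None = None,
        min_samples_split: float = 4,
        min_samples_leaf: float = 2,
        pruning_z: float | None = 0.674,
    ):
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.pruning_z = pruning_z

    def _best_split(self, X, y, w):
        """Vectorized gain-ratio scan over all features."""
        W = w.sum()
        counts = self._leaf_counts(y, w)
        h_parent = _entropy(counts)
        best = (0.0, -1, 0.0)  # (gain_ratio, feature, threshold)
        onehot = np.zeros((len(y), len(self.classes_)))
        onehot[np.arange(len(y)), y] = 1.0
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="mergesort")
            xs = X[order, j]
            ws = w[order]
            cw = onehot[order] * ws[:, None]
            cum = np.cumsum(cw, axis=0)
            cum_w = np.cumsum(ws)
            # candidate split after position i (0-based, left = [0..i])
            valid = np.nonzero(np.diff(xs) > 0)[0]
            if len(valid) == 0:
                continue
            left_w = cum_w[valid]
            right_w = W - left_w
            ok = (left_w >= self.min_samples_leaf) & (
                right_w >= self.min_samples_leaf
            )
            valid = valid[ok]
            if len(valid) == 0:
                continue
            left_c = cum[valid]
            right_c = counts[None, :] - left_c
            left_w = cum_w[valid]
            right_w = W - left_w

            def h(c, tot):
                with np.errstate(divide="ignore", invalid="ignore"):
                    p = c / tot[:, None]
                    t = np.where(p > 0, -p * np.log2(p), 0.0)
                return t.sum(axis=1)

            gain = h_parent - (left_w * h(left_c, left_w)
                               + right_w * h(right_c, right_w)) / W
            pl, pr = left_w / W, right_w / W
            split_info = -(pl * np.log2(pl) + pr * np.log2(pr))
            with np.errstate(divide="ignore", invalid="ignore"):
                gr = np.where((split_info > 0) & (gain > 1e-12),
                              gain / split_info, 0.0)
            k = int(np.argmax(gr))
            if gr[k] > best[0]:
                thr = (xs[valid[k]] + xs[valid[k] + 1]) / 2
                best = (float(gr[k]), j, float(thr))
        return best

    def _grow(self, X, y, w, depth):
        counts = self._leaf_counts(y, w)
        node = _Node(counts=counts, n=w.sum())
        if (
            (self.max_depth is not None and depth >= self.max_depth)
            or w.sum() < self.min_samples_split
            or (counts > 0).sum() <= 1
        ):
            return node
        gr, j, thr = self._best_split(X, y, w)
        if j < 0:
            return node
        mask = X[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = self._grow(X[mask], y[mask], w[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], w[~mask], depth + 1)
        return node

    def _postprocess(self, X, y, w):
        if self.pruning_z is not None:
            self._prune(self.tree_)

    def _prune(self, node: _Node) -> float:
        """Bottom-up pessimistic pruning; returns the subtree's error bound."""
        leaf_err = _pessimistic_errors(
            node.n, node.n - node.counts.max(), self.pruning_z
        )
        if node.is_leaf:
            return leaf_err
        subtree_err = self._prune(node.left) + self._prune(node.right)
        if leaf_err <= subtree_err + 0.1:
            node.make_leaf()
            return leaf_err
        return subtree_err


class UnbiasedUnivariateTreeClassifier(_TreeBase):
    """Binary-split tree with ANOVA-based unbiased variable selection.

    At each node the split variable is the feature with the smallest
    one-way ANOVA F-test p-value across the node's classes; the split
    point is the midpoint of the two superclass means.  Growth stops when
    the best Bonferroni-adjusted p-value exceeds ``alpha``.
    """

    def __init__(
        self,
        max_depth: int | None = None,
        min_samples_split: float = 10,
        min_samples_leaf: float = 2,
        alpha: float = 0.05,
    ):
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.alpha = alpha

    def _select_feature(self, X, y):
        present = np.unique(y)
        if len(present) < 2:
            return -1, 1.0
        best_p, best_j = np.inf, -1
        for j in range(X.shape[1]):
            groups = [X[y == c, j] for c in present]
            if any(len(g) < 2 for g in groups):
                continue
            if all(np.ptp(g) == 0 for g in groups):
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = sps.f_oneway(*groups)
            if np.isnan(p):
                continue
            if p < best_p:
                best_p, best_j = p, j
        return best_j, min(best_p * X.shape[1], 1.0)  # Bonferroni

    def _split_point(self, x, y):
        present = np.unique(y)
        means = np.array([x[y == c].mean() for c in present])
        if len(present) == 2:
            g1, g2 = means
        else:
            # 2-means on the class means -> two superclasses
            order = np.argsort(means)
            gaps = np.diff(means[order])
            cut = int(np.argmax(gaps)) + 1
            g1 = means[order[:cut]].mean()
            g2 = means[order[cut:]].mean()
        return float((g1 + g2) / 2)

    def _grow(self, X, y, w, depth):
        counts = self._leaf_counts(y, w)
        node = _Node(counts=counts, n=w.sum())
        if (
            (self.max_depth is not None and depth >= self.max_depth)
            or w.sum() < self.min_samples_split
            or (counts > 0).sum() <= 1
        ):
            return node
        j, p = self._select_feature(X, y)
        if j < 0 or p > self.alpha:
            return node
        thr = self._split_point(X[:, j], y)
        mask = X[:, j] <= thr
        wl, wr = w[mask].sum(), w[~mask].sum()
        if wl < self.min_samples_leaf or wr < self.min_samples_leaf:
            return node
        node.feature, node.threshold = j, thr
        node.left = self._grow(X[mask], y[mask], w[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], w[~mask], depth + 1)
        return node
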