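"""Entropy-split decision trees for numeric features, binary or multiclass.

Three variants used as ensemble bases:

* gain-ratio splits + pessimistic (confidence-bound) subtree pruning,
* information-gain splits + reduced-error pruning on an internal holdout,
* per-node random feature subsets of size ceil(log2(F) + 1), unpruned.

Behavioural equivalence with any particular toolkit is not claimed; the
algorithms are the textbook ones.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaincinv

__all__ = ["DecisionTree"]


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "counts")

    def __init__(self, counts):
        self.feature = -1
        self.threshold = 0.0
        self.left = None
        self.right = None
        self.counts = counts

    @property
    def is_leaf(self):
        return self.left is None

    def n_nodes(self):
        if self.is_leaf:
            return 1
        return 1 + self.left.n_nodes() + self.right.n_nodes()


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(y, minlength=k).astype(float)


def _neg_xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = -p[nz] * np.log2(p[nz])
    return out


def _best_split_all(X: np.ndarray, y: np.ndarray, k: int, criterion: str):
    """Best (feature, threshold) over all columns of ``X``, or None.

    One vectorized sweep: every column is sorted, cumulative class counts
    give left/right entropies at every cut position of every feature at
    once.
    """
    n, n_feat = X.shape
    if n < 2:
        return None
    order = np.argsort(X, axis=0, kind="mergesort")
    xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]
    valid = xs[:-1] < xs[1:]          # cut after row i keeps xs distinct
    if not valid.any():
        return None
    nl = np.arange(1, n, dtype=float)[:, None]
    nr = float(n) - nl
    parent_counts = np.bincount(y, minlength=k).astype(float)
    h_parent = _entropy(parent_counts)
    hl = np.zeros((n - 1, n_feat))
    hr = np.zeros((n - 1, n_feat))
    for c in range(k):
        cum = np.cumsum(ys == c, axis=0)[:-1]
        hl += _neg_xlog2x(cum / nl)
        hr += _neg_xlog2x((parent_counts[c] - cum) / nr)
    gain = h_parent - (nl * hl + nr * hr) / n
    if criterion == "gain_ratio":
        pl = nl / n
        split_info = _neg_xlog2x(pl) + _neg_xlog2x(1.0 - pl)
        score = np.where(gain > 1e-12, gain / np.maximum(split_info, 1e-12),
                         -np.inf)
    else:
        score = gain.copy()
    score[~valid] = -np.inf
    flat = int(np.argmax(score))
    i, f = np.unravel_index(flat, score.shape)
    if not np.isfinite(score[i, f]) or gain[i, f] <= 1e-12:
        return None
    thr = (xs[i, f] + xs[i + 1, f]) / 2.0
    return int(f), float(thr)


def _c45_error_bound(errors: float, n: float, cf: float = 0.25) -> float:
    """Upper confidence limit of the binomial error rate (C4.5 style)."""
    if n == 0:
        return 0.0
    if errors >= n:
        return 1.0
    return float(betaincinv(errors + 1.0, n - errors, 1.0 - cf))


class DecisionTree:
    """scikit-learn-ish estimator: fit / predict / predict_proba / classes_.

    Parameters
    ----------
    criterion : 'info_gain' or 'gain_ratio'
    pruning : None, 'pessimistic' or 'reduced_error'
    max_features : None (all) or 'log2plus1' (random-tree behaviour)
    """

    def __init__(self, criterion: str = "info_gain", pruning: str | None = None,
                 max_features: str | None = None, min_samples_split: int = 2,
                 max_depth: int | None = None, holdout_fraction: float = 1 / 3,
                 random_state: int = 0):
        if criterion not in ("info_gain", "gain_ratio"):
            raise ValueError(f"unknown criterion {criterion!r}")
        if pruning not in (None, "pessimistic", "reduced_error"):
            raise ValueError(f"unknown pruning {pruning!r}")
        self.criterion = criterion
        self.pruning = pruning
        self.max_features = max_features
        self.min_samples_split = min_samples_split
        self.max_depth = max_depth
        self.holdout_fraction = holdout_fraction
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _grow(self, X, y, depth, rng):
        k = len(self.classes_)
        node = _Node(_class_counts(y, k))
        if (len(y) < self.min_samples_split
                or (self.max_depth is not None and depth >= self.max_depth)
                or len(np.unique(y)) == 1):
            return node
        n_feat = X.shape[1]
        if self.max_features == "log2plus1":
            m = min(n_feat, int(np.ceil(np.log2(n_feat) + 1)) if n_feat > 1
                    else 1)
            candidates = rng.choice(n_feat, size=m, replace=False)
            res = _best_split_all(X[:, candidates], y, k, self.criterion)
            if res is None:
                return node
            f, thr = int(candidates[res[0]]), res[1]
        else:
            res = _best_split_all(X, y, k, self.criterion)
            if res is None:
                return node
            f, thr = res
        mask = X[:, f] <= thr
        node.feature = int(f)
        node.threshold = float(thr)
        node.left = self._grow(X[mask], y[mask], depth + 1, rng)
        node.right = self._grow(X[~mask], y[~mask], depth + 1, rng)
        return node

    # -- pruning -----------------------------------------------------------

    def _pessimistic_errors(self, node) -> float:
        n = node.counts.sum()
        if node.is_leaf:
            e = n - node.counts.max()
            return _c45_error_bound(e, n) * n
        return (self._pessimistic_errors(node.left)
                + self._pessimistic_errors(node.right))

    def _prune_pessimistic(self, node):
        if node.is_leaf:
            return node
        node.left = self._prune_pessimistic(node.left)
        node.right = self._prune_pessimistic(node.right)
        n = node.counts.sum()
        leaf_err = _c45_error_bound(n - node.counts.max(), n) * n
        if leaf_err <= self._pessimistic_errors(node) + 1e-12:
            return _Node(node.counts)
        return node

    def _prune_reduced_error(self, node, X_val, y_val):
        if node.is_leaf:
            return node
        mask = X_val[:, node.feature] <= node.threshold
        node.left = self._prune_reduced_error(node.left, X_val[mask],
                                              y_val[mask])
        node.right = self._prune_reduced_error(node.right, X_val[~mask],
                                               y_val[~mask])
        if len(y_val) == 0:
            return _Node(node.counts)  # unreachable subtree: collapse
        subtree_err = np.sum(self._route(node, X_val) != y_val)
        leaf_err = np.sum(y_val != int(np.argmax(node.counts)))
        if leaf_err <= subtree_err:
            return _Node(node.counts)
        return node

    # -- inference ---------------------------------------------------------

    def _route(self, node, X):
        out = np.empty(len(X), dtype=int)
        self._route_into(node, X, np.arange(len(X)), out)
        return out

    def _route_into(self, node, X, idx, out):
        if node.is_leaf:
            out[idx] = int(np.argmax(node.counts))
            return
        mask = X[idx, node.feature] <= node.threshold
        self._route_into(node.left, X, idx[mask], out)
        self._route_into(node.right, X, idx[~mask], out)

    def _leaf_counts(self, node, X, idx, out):
        if node.is_leaf:
            out[idx] = node.counts
            return
        mask = X[idx, node.feature] <= node.threshold
        self._leaf_counts(node.left, X, idx[mask], out)
        self._leaf_counts(node.right, X, idx[~mask], out)

    # -- public API --------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        if self.pruning == "reduced_error" and len(y) >= 6:
            # stratified internal holdout of ~holdout_fraction
            val_idx = []
            for c in range(len(self.classes_)):
                cls = np.nonzero(y_enc == c)[0]
                cls = rng.permutation(cls)
                n_val = max(1, int(round(len(cls) * self.holdout_fraction)))
                val_idx.extend(cls[:n_val])
            val_mask = np.zeros(len(y), dtype=bool)
            val_mask[val_idx] = True
            root = self._grow(X[~val_mask], y_enc[~val_mask], 0, rng)
            self.n_nodes_pre_prune_ = root.n_nodes()
            root = self._prune_reduced_error(root, X[val_mask],
                                             y_enc[val_mask])
        else:
            root = self._grow(X, y_enc, 0, rng)
            self.n_nodes_pre_prune_ = root.n_nodes()
            if self.pruning == "pessimistic":
                root = self._prune_pessimistic(root)
        self.root_ = root
        self.n_nodes_ = root.n_nodes()
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.classes_[self._route(self.root_, X)]

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        counts = np.empty((len(X), len(self.classes_)))
        self._leaf_counts(self.root_, X, np.arange(len(X)), counts)
        totals = counts.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return counts / totals

    def get_params(self, deep=True):
        return {
            "criterion": self.criterion, "pruning": self.pruning,
            "max_features": self.max_features,
            "min_samples_split": self.min_samples_split,
            "max_depth": self.max_depth,
            "holdout_fraction": self.holdout_fraction,
            "random_state": self.random_state,
        }
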