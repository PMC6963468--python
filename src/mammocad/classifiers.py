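"""Individual classifiers: k-NN, a C4.5-style gain-ratio tree ("J48"),
a random tree, and a random forest.

All classifiers expose the same contract: ``fit(X, y)`` (binary labels
{0, 1}), ``predict(X)``, and ``predict_proba(X)`` returning an (n, 2)
matrix of class probabilities whose rows sum to 1.  ``predict`` is the
argmax of ``predict_proba`` with documented tie rules.  Fits are
deterministic given the seed (random tree / forest) or inherently
(k-NN, J48).

k-NN uses Euclidean distance on features min-max scaled to [0, 1] with
scaling learned from the training data only (the raw features span
several orders of magnitude, so unscaled distances would be dominated by
the variance feature).  The default k is 2; a vote tie is broken by the
nearer neighbour's label, and coincident opposite-label neighbours fall
back to class 0.

The trees split numeric features on midpoint thresholds chosen by gain
ratio.  The random tree considers only ceil(log2(d) + 1) uniformly
sampled features per node and is never pruned; J48 optionally applies
reduced-error pruning against an internal validation split.  The random
forest averages the probabilities of 10 random trees fit on bootstrap
resamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, SchemaError

_EPS = 1e-12


def _check_fitted(model, attr: str) -> None:
    if getattr(model, attr, None) is None:
        raise ParameterError("classifier must be fitted before predicting")


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise SchemaError("X must be n x d and y of length n")
    if not np.isin(y, (0, 1)).all():
        raise SchemaError("labels must be binary {0, 1}")
    return X, y


# ---------------------------------------------------------------------------
# k-nearest neighbours
# ---------------------------------------------------------------------------


class KNNClassifier:
    def __init__(self, k: int = 2):
        if k < 1:
            raise ParameterError("k must be >= 1")
        self.k = k
        self._X = None

    def clone(self) -> "KNNClassifier":
        return KNNClassifier(k=self.k)

    def fit(self, X, y) -> "KNNClassifier":
        X, y = _as_xy(X, y)
        if self.k > X.shape[0]:
            raise ParameterError(f"k={self.k} exceeds the training size {X.shape[0]}")
        self._min = X.min(axis=0)
        rng = X.max(axis=0) - self._min
        self._scale = np.where(rng > 0, rng, 1.0)
        self._X = (X - self._min) / self._scale
        self._y = y
        return self

    def _neighbours(self, Q):
        _check_fitted(self, "_X")
        Q = np.asarray(Q, dtype=float)
        if Q.ndim != 2 or Q.shape[1] != self._X.shape[1]:
            raise SchemaError(
                f"query has {Q.shape[1] if Q.ndim == 2 else '?'} features, "
                f"training has {self._X.shape[1]}"
            )
        d = cdist((Q - self._min) / self._scale, self._X)
        # stable sort: equal distances resolve by training index order
        order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return d, order

    def predict_proba(self, Q) -> np.ndarray:
        _, order = self._neighbours(Q)
        votes1 = self._y[order].mean(axis=1)
        return np.column_stack([1 - votes1, votes1])

    def predict(self, Q) -> np.ndarray:
        d, order = self._neighbours(Q)
        labels = self._y[order]
        votes1 = labels.mean(axis=1)
        pred = (votes1 > 0.5).astype(int)
        ties = np.flatnonzero(votes1 == 0.5)
        for i in ties:
            dn = d[i, order[i]]
            d0 = dn[labels[i] == 0].min()
            d1 = dn[labels[i] == 1].min()
            # nearer neighbour decides; coincident distances -> class 0
            pred[i] = 1 if d1 < d0 else 0
        return pred


# ---------------------------------------------------------------------------
# gain-ratio decision trees
# ---------------------------------------------------------------------------


def binary_entropy(counts) -> float:
    """Entropy (bits) of a class-count vector."""
    c = np.asarray(counts, dtype=float)
    tot = c.sum()
    if tot == 0:
        return 0.0
    p = c[c > 0] / tot
    return float(-(p * np.log2(p)).sum())


def gain_ratio(y, mask_left) -> tuple[float, float]:
    """(information gain, gain ratio) of a boolean split of labels ``y``."""
    y = np.asarray(y)
    left, right = y[mask_left], y[~np.asarray(mask_left)]
    n = y.size
    parent = binary_entropy(np.bincount(y, minlength=2))
    child = (
        left.size / n * binary_entropy(np.bincount(left, minlength=2))
        + right.size / n * binary_entropy(np.bincount(right, minlength=2))
    )
    gain = parent - child
    split_info = binary_entropy([left.size, right.size])
    return gain, (gain / split_info if split_info > _EPS else 0.0)


def _best_split(X, y, feat_idx):
    """Best (feature, threshold) by gain ratio among candidate features.

    Thresholds are midpoints between consecutive distinct sorted values.
    Ties break toward the lower feature index, then the lower threshold.
    Returns None when no split has positive information gain.
    """
    n = y.size
    parent = binary_entropy(np.bincount(y, minlength=2))
    best = None  # (ratio, feature, threshold)
    for f in feat_idx:
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        distinct = np.flatnonzero(np.diff(xs) > 0)
        if distinct.size == 0:
            continue
        pos_left = np.cumsum(ys == 1)[distinct]
        n_left = distinct + 1
        neg_left = n_left - pos_left
        pos_tot, neg_tot = int((y == 1).sum()), int((y == 0).sum())
        for nl, pl, ngl, cut in zip(n_left, pos_left, neg_left, distinct):
            nr = n - nl
            child = (
                nl / n * binary_entropy([pl, ngl])
                + nr / n * binary_entropy([pos_tot - pl, neg_tot - ngl])
            )
            gain = parent - child
            if gain <= _EPS:
                continue
            split_info = binary_entropy([nl, nr])
            ratio = gain / split_info if split_info > _EPS else 0.0
            thr = (xs[cut] + xs[cut + 1]) / 2.0
            key = (ratio, -f, -thr)
            if best is None or key > (best[0], -best[1], -best[2]):
                best = (ratio, f, thr)
    return None if best is None else (best[1], best[2])


@dataclass
class _Node:
    proba: np.ndarray  # class frequencies at this node's training data
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _leaf_proba(y) -> np.ndarray:
    counts = np.bincount(y, minlength=2).astype(float)
    tot = counts.sum()
    return counts / tot if tot else np.array([0.5, 0.5])


class _TreeBase:
    """Shared fit/predict machinery for the gain-ratio trees."""

    def __init__(self, min_leaf: int = 2, max_depth: int | None = None):
        if min_leaf < 1:
            raise ParameterError("min_leaf must be >= 1")
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self._root: Optional[_Node] = None

    def _node_features(self, d: int, rng) -> list[int]:
        return list(range(d))

    def _build(self, X, y, depth, rng) -> _Node:
        node = _Node(proba=_leaf_proba(y))
        if (
            y.size < self.min_leaf
            or len(np.unique(y)) == 1
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return node
        split = _best_split(X, y, self._node_features(X.shape[1], rng))
        if split is None:
            return node
        f, thr = split
        mask = X[:, f] <= thr
        node.feature, node.threshold = f, thr
        node.left = self._build(X[mask], y[mask], depth + 1, rng)
        node.right = self._build(X[~mask], y[~mask], depth + 1, rng)
        return node

    def _row_proba(self, row) -> np.ndarray:
        node = self._root
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        return node.proba

    def predict_proba(self, Q) -> np.ndarray:
        _check_fitted(self, "_root")
        Q = np.asarray(Q, dtype=float)
        return np.array([self._row_proba(r) for r in Q])

    def predict(self, Q) -> np.ndarray:
        # argmax with ties to the lower class index
        return np.argmax(self.predict_proba(Q), axis=1)

    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))

        _check_fitted(self, "_root")
        return _d(self._root)

    def n_leaves(self) -> int:
        def _n(node):
            return 1 if node.is_leaf else _n(node.left) + _n(node.right)

        _check_fitted(self, "_root")
        return _n(self._root)


class J48Tree(_TreeBase):
    """Greedy top-down gain-ratio tree with optional reduced-error pruning.

    With ``prune=True`` a stratified quarter of the training data is held
    out; subtrees whose validation errors do not beat their majority-leaf
    replacement are collapsed bottom-up.
    """

    def __init__(
        self,
        min_leaf: int = 2,
        max_depth: int | None = None,
        prune: bool = True,
        val_frac: float = 0.25,
        seed: int = 0,
    ):
        super().__init__(min_leaf=min_leaf, max_depth=max_depth)
        self.prune = prune
        self.val_frac = val_frac
        self.seed = seed

    def clone(self) -> "J48Tree":
        return J48Tree(
            min_leaf=self.min_leaf,
            max_depth=self.max_depth,
            prune=self.prune,
            val_frac=self.val_frac,
            seed=self.seed,
        )

    def fit(self, X, y) -> "J48Tree":
        X, y = _as_xy(X, y)
        train_idx = np.arange(y.size)
        val_idx = np.array([], dtype=int)
        if self.prune and y.size >= 8 and len(np.unique(y)) == 2:
            rng = np.random.default_rng(self.seed)
            val_parts = []
            for cls in (0, 1):
                idx = np.flatnonzero(y == cls)
                n_val = int(round(self.val_frac * idx.size))
                if 0 < n_val < idx.size:
                    val_parts.append(rng.permutation(idx)[:n_val])
            if val_parts:
                val_idx = np.sort(np.concatenate(val_parts))
                train_idx = np.setdiff1d(np.arange(y.size), val_idx)
        self._root = self._build(X[train_idx], y[train_idx], 0, None)
        if val_idx.size:
            self._rep_prune(self._root, X[val_idx], y[val_idx])
        return self

    def _rep_prune(self, node: _Node, Xv, yv) -> int:
        """Bottom-up reduced-error pruning; returns validation errors at node."""
        leaf_pred = int(np.argmax(node.proba))
        leaf_err = int((yv != leaf_pred).sum())
        if node.is_leaf:
            return leaf_err
        mask = Xv[:, node.feature] <= node.threshold
        sub_err = self._rep_prune(node.left, Xv[mask], yv[mask]) + self._rep_prune(
            node.right, Xv[~mask], yv[~mask]
        )
        if leaf_err <= sub_err:
            node.feature = node.threshold = node.left = node.right = None
            return leaf_err
        return sub_err


class RandomTree(_TreeBase):
    """Unpruned gain-ratio tree considering ceil(log2(d)+1) random features
    per node."""

    def __init__(self, min_leaf: int = 2, max_depth: int | None = None, seed: int = 0):
        super().__init__(min_leaf=min_leaf, max_depth=max_depth)
        self.seed = seed

    def clone(self) -> "RandomTree":
        return RandomTree(min_leaf=self.min_leaf, max_depth=self.max_depth, seed=self.seed)

    def _node_features(self, d: int, rng) -> list[int]:
        m = min(d, int(math.ceil(math.log2(d) + 1))) if d > 1 else 1
        return sorted(rng.choice(d, size=m, replace=False).tolist())

    def fit(self, X, y, rng: np.random.Generator | None = None) -> "RandomTree":
        X, y = _as_xy(X, y)
        if rng is None:
            rng = np.random.default_rng(self.seed)
        self._root = self._build(X, y, 0, rng)
        return self


class RandomForest:
    """Average of ``n_trees`` random trees on bootstrap resamples."""

    def __init__(
        self,
        n_trees: int = 10,
        min_leaf: int = 2,
        max_depth: int | None = None,
        bootstrap: bool = True,
        seed: int = 0,
    ):
        if n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.bootstrap = bootstrap
        self.seed = seed
        self.members_: Optional[list[RandomTree]] = None

    def clone(self) -> "RandomForest":
        return RandomForest(
            n_trees=self.n_trees,
            min_leaf=self.min_leaf,
            max_depth=self.max_depth,
            bootstrap=self.bootstrap,
            seed=self.seed,
        )

    def fit(self, X, y) -> "RandomForest":
        X, y = _as_xy(X, y)
        rng = np.random.default_rng(self.seed)
        self.members_ = []
        for _ in range(self.n_trees):
            idx = rng.choice(y.size, size=y.size, replace=True) if self.bootstrap else np.arange(y.size)
            tree = RandomTree(min_leaf=self.min_leaf, max_depth=self.max_depth)
            tree.fit(X[idx], y[idx], rng=rng)
            self.members_.append(tree)
        return self

    def predict_proba(self, Q) -> np.ndarray:
        _check_fitted(self, "members_")
        return np.mean([m.predict_proba(Q) for m in self.members_], axis=0)

    def predict(self, Q) -> np.ndarray:
        return np.argmax(self.predict_proba(Q), axis=1)


# ---------------------------------------------------------------------------
# factory
# ---------------------------------------------------------------------------

_KINDS = ("knn", "j48", "random_tree", "random_forest")


def make_classifier(kind: str, **params):
    """Fresh unfitted classifier of the given kind ('knn', 'j48',
    'random_tree', 'random_forest')."""
    if kind == "knn":
        return KNNClassifier(**params)
    if kind == "j48":
        return J48Tree(**params)
    if kind == "random_tree":
        return RandomTree(**params)
    if kind in ("random_forest", "rf"):
        return RandomForest(**params)
    raise ParameterError(f"unknown classifier kind {kind!r}; choose from {_KINDS}")
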