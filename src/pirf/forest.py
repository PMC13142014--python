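"""Random forest with per-feature split-candidate sampling probabilities.

This is a CART-style bagged ensemble whose one departure from the standard
algorithm is the feature-selection step: at every node, the mtry candidate
features are drawn *without replacement with probability proportional to a
per-feature weight vector* rather than uniformly. Uniform weights recover
the standard random forest exactly; features with weight zero can never be
drawn and therefore never appear as split features in any tree.

Splitting uses Gini impurity (binary classification) or variance reduction
(regression); thresholds are midpoints between adjacent distinct observed
values; ties in impurity decrease break toward the lower feature index, then
the lower threshold. There is no depth limit — growth stops on purity, on
node size, or when no valid split exists. Out-of-bag (OOB) predictions
supply the internal error estimate used for mtry tuning and the
permutation-importance scores.

Trees are stored as flat arrays (feature, threshold, children, leaf value),
which makes prediction a vectorized level-by-level descent and keeps the
JSON serialization round-trip exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._tree import (CLASSIFICATION, REGRESSION, apply_kernel,
                    grow_tree_kernel, perm_importance_kernel)
from .errors import DataError, ValidationError

__all__ = ["DecisionTree", "ForestModel", "ImportanceVector", "grow_forest",
           "predict", "oob_error", "permutation_importance",
           "default_min_node_size"]

TASKS = ("classification", "regression")


def default_min_node_size(task: str) -> int:
    """1 for classification, 5 for regression (the usual RF defaults)."""
    return 1 if task == "classification" else 5


# ---------------------------------------------------------------------------
# tree representation


@dataclass
class DecisionTree:
    """A single CART tree in flat-array form.

    ``feature[i] == -1`` marks node i as a leaf; ``value[i]`` is the leaf
    payload (class-1 proportion for classification, mean response for
    regression). Internal nodes route x left iff ``x[feature] <= threshold``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    bootstrap_idx: np.ndarray
    oob_idx: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index reached by every row of X."""
        return apply_kernel(self.feature, self.threshold, self.left,
                            self.right, np.ascontiguousarray(X, dtype=float))

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.apply(X)]

    @property
    def features_used(self) -> np.ndarray:
        f = self.feature
        return np.unique(f[f >= 0])


@dataclass
class ForestModel:
    """A trained weighted-feature-sampling random forest."""

    trees: list
    task: str
    mtry: int
    n_trees: int
    selection_probabilities: np.ndarray
    min_node_size: int
    seed: Optional[int]
    classes_: Optional[np.ndarray] = None     # classification only, sorted
    feature_names: Optional[tuple] = None
    oob_error_: Optional[float] = None

    @property
    def n_features(self) -> int:
        return self.selection_probabilities.shape[0]

    # -- prediction ------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} features, got "
                f"{X.shape[1] if X.ndim == 2 else X.ndim}")
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Averaged class proportions, shape (n, 2), column order classes_."""
        if self.task != "classification":
            raise ValidationError("predict_proba requires a classification forest")
        X = self._check_X(X)
        p1 = np.zeros(X.shape[0])
        for t in self.trees:
            p1 += t.predict_value(X)
        p1 /= len(self.trees)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        """Majority vote (classification, ties to the smaller class label)
        or mean of tree predictions (regression)."""
        X = self._check_X(X)
        if self.task == "regression":
            out = np.zeros(X.shape[0])
            for t in self.trees:
                out += t.predict_value(X)
            return out / len(self.trees)
        votes = np.zeros(X.shape[0])
        for t in self.trees:
            votes += (t.predict_value(X) > 0.5)
        majority = votes > len(self.trees) / 2.0   # tie -> class 0
        return self.classes_[majority.astype(int)]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "pirf-forest",
            "version": 1,
            "task": self.task,
            "mtry": int(self.mtry),
            "n_trees": int(self.n_trees),
            "min_node_size": int(self.min_node_size),
            "seed": self.seed,
            "oob_error": self.oob_error_,
            "classes": None if self.classes_ is None else
                       [_jsonable(c) for c in self.classes_],
            "feature_names": None if self.feature_names is None
                             else list(self.feature_names),
            "selection_probabilities": self.selection_probabilities.tolist(),
            "trees": [{
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "value": t.value.tolist(),
                "bootstrap_idx": t.bootstrap_idx.tolist(),
                "oob_idx": t.oob_idx.tolist(),
            } for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForestModel":
        if d.get("format") != "pirf-forest":
            raise ValidationError("not a pirf forest serialization")
        trees = [DecisionTree(
            feature=np.asarray(t["feature"], dtype=np.int32),
            threshold=np.asarray(t["threshold"], dtype=float),
            left=np.asarray(t["left"], dtype=np.int32),
            right=np.asarray(t["right"], dtype=np.int32),
            value=np.asarray(t["value"], dtype=float),
            bootstrap_idx=np.asarray(t["bootstrap_idx"], dtype=np.intp),
            oob_idx=np.asarray(t["oob_idx"], dtype=np.intp),
        ) for t in d["trees"]]
        return cls(
            trees=trees, task=d["task"], mtry=d["mtry"], n_trees=d["n_trees"],
            selection_probabilities=np.asarray(d["selection_probabilities"]),
            min_node_size=d["min_node_size"], seed=d["seed"],
            classes_=None if d["classes"] is None else np.asarray(d["classes"]),
            feature_names=None if d["feature_names"] is None
                          else tuple(d["feature_names"]),
            oob_error_=d["oob_error"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ForestModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


@dataclass
class ImportanceVector:
    """Per-feature permutation-importance scores (may be negative)."""

    labels: tuple
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("importance scores must be finite")
        if len(self.labels) != self.scores.shape[0]:
            raise ValidationError("labels/scores length mismatch")


# ---------------------------------------------------------------------------
# growing


def _task_code(task: str) -> int:
    return CLASSIFICATION if task == "classification" else REGRESSION


def _grow_tree(X: np.ndarray, y: np.ndarray, task: str, mtry: int,
               pos_idx: np.ndarray, wpos: np.ndarray, min_node_size: int,
               rng: np.random.Generator) -> DecisionTree:
    """Grow one tree: bootstrap in numpy, node loop in the numba kernel."""
    n = X.shape[0]
    boot = rng.integers(0, n, size=n)
    oob_mask = np.ones(n, dtype=bool)
    oob_mask[boot] = False
    oob = np.flatnonzero(oob_mask)
    feature, threshold, left, right, value = grow_tree_kernel(
        X, y, _task_code(task), int(mtry), pos_idx, wpos,
        int(min_node_size), boot.astype(np.int64), rng)
    return DecisionTree(
        feature=feature, threshold=threshold, left=left, right=right,
        value=value, bootstrap_idx=boot, oob_idx=oob)


def grow_forest(X, y, task: str, mtry: int, n_trees: int,
                weights: Optional[Sequence[float]] = None,
                min_node_size: Optional[int] = None,
                seed: Optional[int] = None,
                feature_names: Optional[Sequence[str]] = None,
                compute_oob: bool = True) -> ForestModel:
    """Grow a forest of ``n_trees`` bagged trees.

    Each tree is grown on a bootstrap sample of size n; at every node,
    min(mtry, #positive-weight features) distinct candidates are drawn
    without replacement with probability proportional to ``weights``
    (uniform when omitted, which reproduces the standard random forest).
    Binary classification labels may be anything orderable; internally the
    lexicographically smaller class is 0.
    """
    if task not in TASKS:
        raise ValidationError(f"task must be one of {TASKS}, got {task!r}")
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D matrix")
    n, p = X.shape
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if mtry < 1:
        raise ValidationError(f"mtry must be >= 1, got {mtry}")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")

    y = np.asarray(y)
    if y.shape[0] != n:
        raise ValidationError("X and y have different numbers of samples")
    classes = None
    if task == "classification":
        classes = np.unique(y)
        if classes.shape[0] == 1:
            raise ValidationError("classification outcome has a single class")
        if classes.shape[0] != 2:
            raise ValidationError(
                f"only binary classification is supported ({classes.shape[0]} "
                "classes found)")
        y_enc = (y == classes[1]).astype(float)
    else:
        y_enc = np.asarray(y, dtype=float)

    if weights is None:
        w = np.full(p, 1.0 / p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (p,):
            raise ValidationError("weights must have one entry per feature")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValidationError("all selection weights are zero")
        if abs(total - 1.0) > 1e-6:
            raise ValidationError("weights must sum to 1")
        w = w / total
    pos_idx = np.flatnonzero(w > 0).astype(np.int64)
    wpos = np.ascontiguousarray(w[pos_idx], dtype=float)

    if min_node_size is None:
        min_node_size = default_min_node_size(task)

    ss = np.random.SeedSequence(seed)
    trees = [
        _grow_tree(X, y_enc, task, mtry, pos_idx, wpos, min_node_size,
                   np.random.default_rng(child))
        for child in ss.spawn(n_trees)
    ]
    model = ForestModel(
        trees=trees, task=task, mtry=int(mtry), n_trees=int(n_trees),
        selection_probabilities=w, min_node_size=int(min_node_size),
        seed=seed, classes_=classes,
        feature_names=None if feature_names is None else tuple(feature_names))
    if compute_oob:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.oob_error_ = oob_error(model, X, y)
    return model


def predict(model: ForestModel, X_new):
    """Functional alias for :meth:`ForestModel.predict`."""
    return model.predict(X_new)


# ---------------------------------------------------------------------------
# OOB error and permutation importance


def _encode_y(model: ForestModel, y) -> np.ndarray:
    if model.task == "classification":
        return (np.asarray(y) == model.classes_[1]).astype(float)
    return np.asarray(y, dtype=float)


def oob_error(model: ForestModel, X, y) -> float:
    """Out-of-bag error: misclassification rate of OOB-aggregated votes
    (classification) or MSE of OOB-aggregated means (regression).

    Samples that are never OOB are excluded from the average with a warning.
    """
    X = model._check_X(X)
    y_enc = _encode_y(model, y)
    n = X.shape[0]
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for t in model.trees:
        if t.oob_idx.size == 0:
            continue
        vals = t.predict_value(X[t.oob_idx])
        if model.task == "classification":
            acc[t.oob_idx] += (vals > 0.5)
        else:
            acc[t.oob_idx] += vals
        cnt[t.oob_idx] += 1
    covered = cnt > 0
    if not covered.any():
        raise DataError("no sample is out-of-bag for any tree")
    if not covered.all():
        warnings.warn(f"{int((~covered).sum())} samples never out-of-bag; "
                      "excluded from the OOB error", stacklevel=2)
    if model.task == "classification":
        pred1 = acc[covered] > cnt[covered] / 2.0      # vote tie -> class 0
        return float(np.mean(pred1 != (y_enc[covered] > 0.5)))
    return float(np.mean((acc[covered] / cnt[covered] - y_enc[covered]) ** 2))


def permutation_importance(model: ForestModel, X, y,
                           n_permutations: int = 1,
                           seed: Optional[int] = None) -> ImportanceVector:
    """OOB permutation importance.

    For each tree and each feature the tree uses, the feature's OOB column is
    permuted and the increase in that tree's OOB loss (error rate or MSE)
    recorded; scores are averaged over ``n_permutations`` repetitions and
    over all trees, with trees that never use a feature contributing 0 for it.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    X = model._check_X(X)
    y_enc = _encode_y(model, y)
    p = model.n_features
    task = _task_code(model.task)
    scores = np.zeros(p)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for tree in model.trees:
        oob = tree.oob_idx
        if oob.size == 0:
            continue
        Xo = np.ascontiguousarray(X[oob])
        yo = np.ascontiguousarray(y_enc[oob])
        scores += perm_importance_kernel(
            tree.feature, tree.threshold, tree.left, tree.right, tree.value,
            Xo, yo, task, tree.features_used.astype(np.int64),
            int(n_permutations), rng)
    scores /= len(model.trees)
    labels = model.feature_names or tuple(f"x{j}" for j in range(p))
    return ImportanceVector(labels=tuple(labels), scores=scores)
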