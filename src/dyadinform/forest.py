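"""Regression random forest with depth-weighted split-frequency importance.

The forest is a conventional ensemble of CART regression trees grown on
without-replacement subsamples, with ``mtry`` candidate predictors per node
and greedy variance-reduction splitting.  Its purpose here is the importance
statistic: for each depth level the relative frequency with which each
predictor is chosen for splitting, pooled across trees, is combined into a
weighted average in which splits higher in the tree (closer to the root)
carry more weight.  The resulting vector is non-negative and sums to one,
so it reads as a share of the forest's early splitting decisions.

Everything is deterministic given the configuration seed: per-tree random
streams are spawned from a single seed sequence.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import MalformedInputError

__all__ = [
    "ForestConfig",
    "TreeNode",
    "DepthWeightedForestRegressor",
    "fit_tree",
    "fit_forest",
    "predict",
    "split_importance",
    "forest_to_json",
    "forest_from_json",
]


@dataclass
class ForestConfig:
    """Hyperparameters of the forest and of the importance statistic.

    ``max_importance_depth`` caps the depths entering the importance
    statistic (root depth = 1) and ``decay_exponent`` sets how fast the
    per-depth weight ``d**-decay_exponent`` decays; the defaults weigh a
    root split 16 times a depth-4 split.
    """

    n_trees: int = 500
    mtry: int | None = None  # default ceil(p / 3), resolved at fit time
    min_node_size: int = 5
    subsample_fraction: float = 0.5
    max_importance_depth: int = 4
    decay_exponent: float = 2.0
    seed: int = 0

    def validate(self, p: int | None = None) -> None:
        if self.n_trees < 1:
            raise MalformedInputError("n_trees must be >= 1")
        if self.min_node_size < 1:
            raise MalformedInputError("min_node_size must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise MalformedInputError("subsample_fraction must be in (0, 1]")
        if self.max_importance_depth < 1:
            raise MalformedInputError("max_importance_depth must be >= 1")
        if self.decay_exponent < 0:
            raise MalformedInputError("decay_exponent must be >= 0")
        if self.mtry is not None and self.mtry < 1:
            raise MalformedInputError("mtry must be >= 1")
        if p is not None and self.mtry is not None and self.mtry > p:
            raise MalformedInputError("mtry cannot exceed the predictor count")

    def resolved_mtry(self, p: int) -> int:
        return self.mtry if self.mtry is not None else max(1, math.ceil(p / 3))


@dataclass
class TreeNode:
    """One node of a regression tree; root has depth 1.

    Internal nodes carry (split_variable, threshold, left, right); rows with
    ``x[split_variable] <= threshold`` go left.  Leaves carry the mean
    response of the training rows that reached them.
    """

    depth: int
    prediction: float | None = None
    split_variable: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None


def _best_split(X: np.ndarray, y: np.ndarray, features: np.ndarray,
                min_node: int) -> tuple[int, float, float] | None:
    """Exhaustive best (variable, threshold) over the sampled features.

    Maximises the between-child variance reduction
    ``n_L * n_R / n * (mean_L - mean_R)**2``.  Thresholds sit at midpoints
    between adjacent distinct sorted values; only splits leaving both
    children at least ``min_node`` rows are eligible.  Ties break toward the
    lowest feature index, then the lowest threshold.
    """
    n = y.shape[0]
    best = None  # (gain, feature, threshold)
    for j in np.sort(features):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs, ys = xj[order], y[order]
        # candidate cut after position i (1-based left count i+1)
        csum = np.cumsum(ys)
        total = csum[-1]
        n_left = np.arange(1, n)
        valid = (xs[1:] != xs[:-1]) & (n_left >= min_node) & (n - n_left >= min_node)
        if not valid.any():
            continue
        sum_left = csum[:-1]
        n_l = n_left[valid].astype(float)
        n_r = n - n_l
        mean_l = sum_left[valid] / n_l
        mean_r = (total - sum_left[valid]) / n_r
        gains = n_l * n_r / n * (mean_l - mean_r) ** 2
        k = int(np.argmax(gains))  # first max = lowest threshold
        gain = float(gains[k])
        if gain <= 0.0:
            continue
        idx = np.flatnonzero(valid)[k]
        thr = float((xs[idx] + xs[idx + 1]) / 2.0)
        if best is None or gain > best[0]:
            best = (gain, int(j), thr)
    if best is None:
        return None
    return best[1], best[2], best[0]


def fit_tree(X: np.ndarray, y: np.ndarray, cfg: ForestConfig,
             rng: np.random.Generator) -> TreeNode:
    """Grow one greedy CART regression tree on the given rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise MalformedInputError("X must be a non-empty 2-D array")
    if X.shape[0] != y.shape[0]:
        raise MalformedInputError("X and y row counts differ")
    if np.isnan(X).any() or np.isnan(y).any():
        raise MalformedInputError("missing values are not allowed in X or y")
    cfg.validate(p=X.shape[1])
    mtry = cfg.resolved_mtry(X.shape[1])

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yn = y[idx]
        node = TreeNode(depth=depth, prediction=float(yn.mean()))
        if idx.size < 2 * cfg.min_node_size or np.all(yn == yn[0]):
            return node
        features = rng.choice(X.shape[1], size=min(mtry, X.shape[1]),
                              replace=False)
        found = _best_split(X[idx], yn, features, cfg.min_node_size)
        if found is None:
            return node
        j, thr, _ = found
        go_left = X[idx, j] <= thr
        node.split_variable = j
        node.threshold = thr
        node.prediction = None
        node.left = grow(idx[go_left], depth + 1)
        node.right = grow(idx[~go_left], depth + 1)
        return node

    return grow(np.arange(X.shape[0]), depth=1)


def fit_forest(X: np.ndarray, y: np.ndarray, cfg: ForestConfig) -> list[TreeNode]:
    """Grow ``cfg.n_trees`` trees, each on a without-replacement subsample.

    Per-tree random streams are spawned deterministically from ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cfg.validate(p=X.shape[1] if X.ndim == 2 else None)
    n = X.shape[0]
    if n == 0:
        raise MalformedInputError("cannot fit a forest on zero rows")
    m = max(1, math.ceil(cfg.subsample_fraction * n))
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trees)
    trees = []
    for t in range(cfg.n_trees):
        rng = np.random.default_rng(streams[t])
        rows = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        trees.append(fit_tree(X[rows], y[rows], cfg, rng))
    return trees


def _predict_tree(node: TreeNode, X: np.ndarray, out: np.ndarray,
                  idx: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] = node.prediction
        return
    go_left = X[idx, node.split_variable] <= node.threshold
    _predict_tree(node.left, X, out, idx[go_left])
    _predict_tree(node.right, X, out, idx[~go_left])


def predict(forest: Sequence[TreeNode], X_new: np.ndarray,
            n_features: int | None = None) -> np.ndarray:
    """Mean over trees of the leaf each tree routes the row to."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if n_features is not None and X_new.shape[1] != n_features:
        raise MalformedInputError(
            f"expected {n_features} predictor columns, got {X_new.shape[1]}")
    acc = np.zeros(X_new.shape[0])
    buf = np.empty(X_new.shape[0])
    idx = np.arange(X_new.shape[0])
    for tree in forest:
        _predict_tree(tree, X_new, buf, idx)
        acc += buf
    return acc / len(forest)


def split_importance(forest: Sequence[TreeNode], p: int,
                     max_depth: int = 4, decay_exponent: float = 2.0) -> np.ndarray:
    """Depth-weighted split-frequency variable importance.

    For each depth ``d <= max_depth`` with at least one split (pooled over
    trees), let ``f[j, d]`` be the share of depth-``d`` internal nodes that
    split on predictor ``j``.  Importance is the weighted mean of the
    ``f[:, d]`` with weights ``d**-decay_exponent``, normalised over the
    occupied depths; it sums to one.  If no tree splits at all, an all-zero
    vector is returned with a warning.
    """
    counts = np.zeros((max_depth, p))
    stack = list(forest)
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        if node.depth <= max_depth:
            counts[node.depth - 1, node.split_variable] += 1
        stack.append(node.left)
        stack.append(node.right)

    totals = counts.sum(axis=1)
    occupied = totals > 0
    if not occupied.any():
        warnings.warn("forest contains no splits; importance is all zero",
                      stacklevel=2)
        return np.zeros(p)
    depths = np.arange(1, max_depth + 1, dtype=float)
    w = depths[occupied] ** (-decay_exponent)
    w = w / w.sum()
    freq = counts[occupied] / totals[occupied, None]
    return w @ freq


# --- sklearn-style estimator facade -----------------------------------------


class DepthWeightedForestRegressor:
    """Regression random forest exposing split-frequency importances.

    Follows the scikit-learn estimator protocol (``fit``/``predict``/
    ``get_params``/``set_params``) so it composes with pipelines and model
    selection.  After ``fit``:

    Attributes
    ----------
    trees_ : list of TreeNode
    n_features_in_ : int
    split_importances_ : ndarray of shape (n_features_in_,)
        Depth-weighted split-frequency importance; sums to 1 whenever the
        forest contains at least one split.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_node_size: int = 5, subsample_fraction: float = 0.5,
                 max_importance_depth: int = 4, decay_exponent: float = 2.0,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.subsample_fraction = subsample_fraction
        self.max_importance_depth = max_importance_depth
        self.decay_exponent = decay_exponent
        self.random_state = random_state

    # -- sklearn protocol --
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_trees", "mtry", "min_node_size", "subsample_fraction",
            "max_importance_depth", "decay_exponent", "random_state")}

    def set_params(self, **params) -> "DepthWeightedForestRegressor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ForestConfig:
        return ForestConfig(
            n_trees=self.n_trees, mtry=self.mtry,
            min_node_size=self.min_node_size,
            subsample_fraction=self.subsample_fraction,
            max_importance_depth=self.max_importance_depth,
            decay_exponent=self.decay_exponent, seed=self.random_state)

    def fit(self, X, y) -> "DepthWeightedForestRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.trees_ = fit_forest(X, y, self._config())
        self.n_features_in_ = X.shape[1]
        self.split_importances_ = split_importance(
            self.trees_, self.n_features_in_,
            self.max_importance_depth, self.decay_exponent)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "trees_"):
            raise MalformedInputError("estimator is not fitted")
        return predict(self.trees_, X, n_features=self.n_features_in_)

    def score(self, X, y) -> float:
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        tot = y - y.mean()
        return 1.0 - float(resid @ resid) / float(tot @ tot)


# --- JSON serialization (for fixtures and audit) -----------------------------


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"depth": node.depth, "prediction": node.prediction}
    return {
        "depth": node.depth,
        "variable": node.split_variable,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if "variable" not in d:
        return TreeNode(depth=d["depth"], prediction=d["prediction"])
    return TreeNode(depth=d["depth"], split_variable=d["variable"],
                    threshold=d["threshold"],
                    left=_node_from_dict(d["left"]),
                    right=_node_from_dict(d["right"]))


def forest_to_json(forest: Sequence[TreeNode]) -> str:
    return json.dumps([_node_to_dict(t) for t in forest])


def forest_from_json(s: str) -> list[TreeNode]:
    return [_node_from_dict(d) for d in json.loads(s)]
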