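"""Independent brute-force oracles, kept deliberately naive.

These re-derive quantities the package computes — exhaustive split search,
explicit node-by-node importance counting, normal-equations OLS — using
plain loops and textbook formulas, so they share no code path with the
implementation they check.
"""

from __future__ import annotations

import numpy as np

from dyadinform.forest import TreeNode


def brute_force_best_split(X: np.ndarray, y: np.ndarray,
                           features, min_node: int):
    """Exhaustive search over all (feature, midpoint threshold) pairs.

    Returns (feature, threshold) of the maximal variance-reduction split
    with ties broken by lowest feature index then lowest threshold, or None.
    """
    n = len(y)
    best = None
    for j in sorted(features):
        uniq = np.unique(X[:, j])
        for a, bb in zip(uniq[:-1], uniq[1:]):
            thr = (a + bb) / 2.0
            left = y[X[:, j] <= thr]
            right = y[X[:, j] > thr]
            if len(left) < min_node or len(right) < min_node:
                continue
            gain = len(left) * len(right) / n * (left.mean() - right.mean()) ** 2
            if gain <= 0:
                continue
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, thr)
    return None if best is None else (best[1], best[2])


def brute_force_importance(forest, p: int, max_depth: int,
                           decay_exponent: float) -> np.ndarray:
    """Explicit node enumeration and per-depth counting."""
    per_depth: dict[int, list[int]] = {}

    def walk(node: TreeNode):
        if node.is_leaf:
            return
        if node.depth <= max_depth:
            per_depth.setdefault(node.depth, []).append(node.split_variable)
        walk(node.left)
        walk(node.right)

    for tree in forest:
        walk(tree)

    if not per_depth:
        return np.zeros(p)
    depths = sorted(per_depth)
    weights = {d: d ** (-decay_exponent) for d in depths}
    wsum = sum(weights.values())
    imp = np.zeros(p)
    for d in depths:
        splits = per_depth[d]
        for j in range(p):
            imp[j] += weights[d] / wsum * splits.count(j) / len(splits)
    return imp


def random_small_forest(rng: np.random.Generator, p: int = 6,
                        n_trees: int = 5, max_depth: int = 4):
    """A structurally random forest (no data) for importance-oracle tests."""

    def grow(depth: int) -> TreeNode:
        if depth >= max_depth or rng.random() < 0.35:
            return TreeNode(depth=depth, prediction=float(rng.normal()))
        return TreeNode(depth=depth,
                        split_variable=int(rng.integers(p)),
                        threshold=float(rng.normal()),
                        left=grow(depth + 1), right=grow(depth + 1))

    return [grow(1) for _ in range(rng.integers(1, n_trees + 1))]


def normal_equations_ols(X: np.ndarray, y: np.ndarray):
    """(X'X)^-1 X'y with textbook standard errors."""
    n = len(y)
    M = np.column_stack([np.ones(n), X])
    XtX_inv = np.linalg.inv(M.T @ M)
    beta = XtX_inv @ M.T @ y
    resid = y - M @ beta
    sigma2 = resid @ resid / (n - M.shape[1])
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    return beta, se, sigma2
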