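"""Reduced-error-pruning regression tree.

Growing: greedy binary splits maximising variance reduction (sum-of-squared-
error decrease), midpoint thresholds, a minimum leaf size and an optional
depth cap. Ties are broken toward the lowest feature index, then the lowest
threshold. Leaf prediction is the mean of the growing-set targets in the leaf.

Pruning: one of ``n_pruning_folds`` internal folds is held out from growing;
bottom-up, any internal node whose pruning-set squared error would not
increase when collapsed to a leaf is collapsed. Pruning-set SSE is therefore
non-increasing throughout the pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["REPTreeParams", "TreeNode", "REPTree", "fit_reptree"]

logger = logging.getLogger(__name__)

_TOL = 1e-12


@dataclass(frozen=True)
class REPTreeParams:
    min_instances_per_leaf: int = 2
    n_pruning_folds: int = 3
    max_depth: int | None = None
    prune: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_instances_per_leaf < 1:
            raise ValueError("min_instances_per_leaf must be >= 1")
        if self.prune and self.n_pruning_folds < 2:
            raise ValueError("n_pruning_folds must be >= 2 when pruning")


@dataclass
class TreeNode:
    value: float
    n: int
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def collapse(self) -> None:
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None

    def to_dict(self) -> dict[str, Any]:
        if self.is_leaf:
            return {"value": self.value, "n": self.n}
        return {
            "value": self.value,
            "n": self.n,
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TreeNode":
        node = cls(value=d["value"], n=d["n"])
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) by SSE reduction; None if no valid split.

    Scans sorted prefix sums per feature; candidate thresholds are midpoints
    of distinct consecutive values. First-seen wins on gain ties, which with
    the ascending scan order realises the lowest-feature, lowest-threshold
    tie-break.
    """
    n, p = X.shape
    if n < 2 * min_leaf:
        return None
    sy, syy = y.sum(), (y * y).sum()
    parent_sse = syy - sy * sy / n

    best: tuple[int, float, float] | None = None
    best_gain = _TOL
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cy = np.cumsum(ys)
        cyy = np.cumsum(ys * ys)
        i = np.arange(min_leaf, n - min_leaf + 1)
        valid = xs[i - 1] < xs[i]
        if not valid.any():
            continue
        i = i[valid]
        sse_l = cyy[i - 1] - cy[i - 1] ** 2 / i
        sse_r = (syy - cyy[i - 1]) - (sy - cy[i - 1]) ** 2 / (n - i)
        gains = parent_sse - sse_l - sse_r
        k = int(np.argmax(gains))
        if gains[k] > best_gain:
            best_gain = float(gains[k])
            thr = float((xs[i[k] - 1] + xs[i[k]]) / 2.0)
            best = (j, thr, best_gain)
    return best


def _grow(
    X: np.ndarray, y: np.ndarray, min_leaf: int, max_depth: int | None, depth: int = 0
) -> TreeNode:
    node = TreeNode(value=float(y.mean()), n=len(y))
    if max_depth is not None and depth >= max_depth:
        return node
    split = _best_split(X, y, min_leaf)
    if split is None:
        return node
    j, thr, _ = split
    mask = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.left = _grow(X[mask], y[mask], min_leaf, max_depth, depth + 1)
    node.right = _grow(X[~mask], y[~mask], min_leaf, max_depth, depth + 1)
    return node


def _prune(node: TreeNode, X: np.ndarray, y: np.ndarray) -> float:
    """Bottom-up reduced-error pruning; returns pruning-set SSE of the subtree."""
    sse_leaf = float(((y - node.value) ** 2).sum())
    if node.is_leaf:
        return sse_leaf
    mask = X[:, node.feature] <= node.threshold
    sse_subtree = _prune(node.left, X[mask], y[mask]) + _prune(
        node.right, X[~mask], y[~mask]
    )
    if sse_leaf <= sse_subtree + _TOL:
        node.collapse()
        return sse_leaf
    return sse_subtree


class REPTree:
    """Fitted variance-reduction regression tree with reduced-error pruning."""

    def __init__(self, root: TreeNode, params: REPTreeParams, n_features: int):
        self.root = root
        self.params = params
        self.n_features = n_features

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected (n, {self.n_features}) feature matrix")
        out = np.empty(len(X))
        self._fill(self.root, X, np.arange(len(X)), out)
        return out

    def _fill(
        self, node: TreeNode, X: np.ndarray, idx: np.ndarray, out: np.ndarray
    ) -> None:
        if node.is_leaf:
            out[idx] = node.value
            return
        mask = X[idx, node.feature] <= node.threshold
        self._fill(node.left, X, idx[mask], out)
        self._fill(node.right, X, idx[~mask], out)

    @property
    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    @property
    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def to_dict(self) -> dict[str, Any]:
        return {"n_features": self.n_features, "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d: dict[str, Any], params: REPTreeParams | None = None) -> "REPTree":
        return cls(
            root=TreeNode.from_dict(d["root"]),
            params=params or REPTreeParams(),
            n_features=d["n_features"],
        )


def fit_reptree(X: np.ndarray, y: np.ndarray, params: REPTreeParams = REPTreeParams()) -> REPTree:
    """Grow and (optionally) prune a regression tree.

    With pruning enabled, a seeded internal fold of ~1/n_pruning_folds of the
    rows is held out from growing and used only to prune.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) with matching y")
    n = len(y)
    if n < 2 * params.min_instances_per_leaf:
        raise ValueError("too few rows to fit a tree")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("features and target must be finite")

    min_leaf = params.min_instances_per_leaf
    if params.prune:
        rng = np.random.default_rng(params.seed)
        perm = rng.permutation(n)
        n_prune = n // params.n_pruning_folds
        if n - n_prune < 2 * min_leaf or n_prune == 0:
            logger.warning("too few rows to hold out a pruning fold; growing on all")
            root = _grow(X, y, min_leaf, params.max_depth)
        else:
            prune_idx = perm[:n_prune]
            grow_idx = perm[n_prune:]
            root = _grow(X[grow_idx], y[grow_idx], min_leaf, params.max_depth)
            _prune(root, X[prune_idx], y[prune_idx])
    else:
        root = _grow(X, y, min_leaf, params.max_depth)
    return REPTree(root=root, params=params, n_features=X.shape[1])
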