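"""Rotation-forest regressor.

Each ensemble member randomly partitions the features into groups of at most
``feature_subset_size``, estimates principal axes per group on a bootstrap
row sample, rotates the full training matrix group-by-group (block-diagonal
orthonormal rotation) and fits a reduced-error-pruning tree on the rotated
features. Prediction is the mean of per-tree predictions on identically
rotated inputs.

The classification-specific class subsampling of the original formulation has
no regression analogue; rows for axis estimation are drawn by plain bootstrap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from thermovine.forest.reptree import REPTree, REPTreeParams, fit_reptree

__all__ = [
    "RotationForestParams",
    "GroupRotation",
    "RotationForestModel",
    "fit_rotation_forest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RotationForestParams:
    n_trees: int = 10
    feature_subset_size: int = 3
    bootstrap_fraction: float = 0.75
    tree_params: REPTreeParams = field(default_factory=REPTreeParams)
    rotation: str = "pca"  # "pca" | "identity"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.feature_subset_size < 1:
            raise ValueError("feature_subset_size must be >= 1")
        if not 0.0 < self.bootstrap_fraction <= 1.0:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.rotation not in ("pca", "identity"):
            raise ValueError("rotation must be 'pca' or 'identity'")


@dataclass
class GroupRotation:
    """Feature grouping plus per-group centring vectors and orthonormal axes."""

    groups: list[np.ndarray]  # feature indices per group
    centers: list[np.ndarray]
    axes: list[np.ndarray]  # (k, k) orthonormal, columns are axes

    def apply(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for g, c, A in zip(self.groups, self.centers, self.axes):
            cols.append((X[:, g] - c) @ A)
        return np.hstack(cols)


def _principal_axes(sub: np.ndarray) -> np.ndarray:
    """Full-rank orthonormal principal axes of a centred sample, sign-fixed."""
    k = sub.shape[1]
    if len(sub) < 2 or float(np.var(sub, axis=0).sum()) < 1e-12:
        logger.warning("degenerate feature group (zero variance); identity axes")
        return np.eye(k)
    cov = np.cov(sub, rowvar=False).reshape(k, k)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axes = eigvecs[:, ::-1]  # descending variance
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    return axes


class RotationForestModel:
    """Ensemble of (rotation, fitted tree) pairs bound to named features."""

    def __init__(
        self,
        feature_names: list[str],
        params: RotationForestParams,
        rotations: list[GroupRotation],
        trees: list[REPTree],
        tree_seeds: list[int],
    ):
        self.feature_names = feature_names
        self.params = params
        self.rotations = rotations
        self.trees = trees
        self.tree_seeds = tree_seeds

    def _as_matrix(self, X: "pd.DataFrame | np.ndarray") -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names) - set(X.columns)
            extra = set(X.columns) - set(self.feature_names)
            if missing or extra:
                raise KeyError(
                    f"feature mismatch: missing {sorted(missing)}, unknown {sorted(extra)}"
                )
            return X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features")
        return X

    def predict_per_tree(self, X: "pd.DataFrame | np.ndarray") -> np.ndarray:
        """(n_trees, n_samples) matrix of member predictions."""
        M = self._as_matrix(X)
        return np.vstack(
            [tree.predict(rot.apply(M)) for rot, tree in zip(self.rotations, self.trees)]
        )

    def predict(self, X: "pd.DataFrame | np.ndarray") -> np.ndarray:
        return self.predict_per_tree(X).mean(axis=0)

    def to_dict(self) -> dict[str, Any]:
        return {
            "feature_names": self.feature_names,
            "params": {
                "n_trees": self.params.n_trees,
                "feature_subset_size": self.params.feature_subset_size,
                "bootstrap_fraction": self.params.bootstrap_fraction,
                "rotation": self.params.rotation,
                "seed": self.params.seed,
            },
            "tree_seeds": self.tree_seeds,
            "members": [
                {
                    "groups": [g.tolist() for g in rot.groups],
                    "centers": [c.tolist() for c in rot.centers],
                    "axes": [a.tolist() for a in rot.axes],
                    "tree": tree.to_dict(),
                }
                for rot, tree in zip(self.rotations, self.trees)
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RotationForestModel":
        params = RotationForestParams(
            n_trees=d["params"]["n_trees"],
            feature_subset_size=d["params"]["feature_subset_size"],
            bootstrap_fraction=d["params"]["bootstrap_fraction"],
            rotation=d["params"]["rotation"],
            seed=d["params"]["seed"],
        )
        rotations, trees = [], []
        for m in d["members"]:
            rotations.append(
                GroupRotation(
                    groups=[np.asarray(g, dtype=int) for g in m["groups"]],
                    centers=[np.asarray(c, dtype=float) for c in m["centers"]],
                    axes=[np.asarray(a, dtype=float) for a in m["axes"]],
                )
            )
            trees.append(REPTree.from_dict(m["tree"]))
        return cls(d["feature_names"], params, rotations, trees, d["tree_seeds"])

    @classmethod
    def load_json(cls, path: str | Path) -> "RotationForestModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_rotation_forest(
    X: "pd.DataFrame | np.ndarray",
    y: Sequence[float],
    params: RotationForestParams = RotationForestParams(),
    feature_names: list[str] | None = None,
) -> RotationForestModel:
    """Fit the ensemble; deterministic given data, params and seed."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(M.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = M.shape
    if n < 10:
        raise ValueError("need at least 10 rows")
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if not 1 <= params.feature_subset_size <= p:
        raise ValueError("feature_subset_size must be in [1, n_features]")

    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_trees)
    n_boot = max(2, int(round(params.bootstrap_fraction * n)))

    rotations, trees, tree_seeds = [], [], []
    for child in children:
        rng = np.random.default_rng(child)
        perm = rng.permutation(p)
        groups = [
            np.sort(perm[i : i + params.feature_subset_size])
            for i in range(0, p, params.feature_subset_size)
        ]
        centers, axes = [], []
        for g in groups:
            boot = rng.choice(n, size=n_boot, replace=True)
            sub = M[np.ix_(boot, g)]
            center = sub.mean(axis=0)
            if params.rotation == "identity":
                centers.append(np.zeros(len(g)))
                axes.append(np.eye(len(g)))
            else:
                centers.append(center)
                axes.append(_principal_axes(sub - center))
        rot = GroupRotation(groups=groups, centers=centers, axes=axes)
        tree_seed = int(child.generate_state(1, dtype=np.uint64)[0]) % (2**32)
        tp = params.tree_params
        tree = fit_reptree(
            rot.apply(M),
            y,
            REPTreeParams(
                min_instances_per_leaf=tp.min_instances_per_leaf,
                n_pruning_folds=tp.n_pruning_folds,
                max_depth=tp.max_depth,
                prune=tp.prune,
                seed=tree_seed,
            ),
        )
        rotations.append(rot)
        trees.append(tree)
        tree_seeds.append(tree_seed)
    return RotationForestModel(feature_names, params, rotations, trees, tree_seeds)
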