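"""Gram matrices from embeddings: linear kernel and random-forest partition kernel.

A random forest can be read as a distribution over partitions of a data set:
pick a tree uniformly at random, pick a truncation depth uniformly between the
root (depth 0, one block containing everything) and the deepest node of that
tree, and cut the tree at that depth — every node at the cut (or every leaf
shallower than it) is one block.  The probability, under this distribution,
that two samples land in the same block is a positive-semidefinite kernel: the
RF partition kernel.  This module builds Gram matrices for that kernel, either
by Monte-Carlo sampling of (tree, depth) partitions or by exhaustive
enumeration (the testing oracle), together with the plain dot-product kernel.

Tree induction itself is delegated to scikit-learn; this module only traverses
the fitted tree structures.  Ties at a split are routed ``x <= threshold`` to
the left child, matching the scikit-learn convention — block identity depends
on this, so it is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import (
    ComplexityCapError,
    DegenerateLabelsError,
    DimensionMismatchError,
    InvalidInputError,
    InvalidModelError,
    InvalidParameterError,
)

__all__ = [
    "EmbeddingMatrix",
    "LabelVector",
    "GramMatrix",
    "ForestParams",
    "TreeStructure",
    "ForestPartitioner",
    "PartitionAssignment",
    "linear_gram",
    "fit_forest",
    "sample_partition",
    "block_ids",
    "rf_gram",
    "exact_rf_gram",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingMatrix:
    """An n_samples x n_features real feature matrix with sample identifiers.

    This is the object whose representation is compared: rows are samples,
    columns are features (fingerprint bits, descriptors, latent dimensions).
    """

    values: np.ndarray
    sample_ids: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidInputError(
                f"embedding must be 2-D (samples x features), got ndim={values.ndim}"
            )
        if values.shape[0] < 2:
            raise InvalidInputError("embedding needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("embedding contains non-finite entries")
        object.__setattr__(self, "values", values)
        ids = self.sample_ids
        if ids is None:
            ids = tuple(range(values.shape[0]))
        else:
            ids = tuple(ids)
        if len(ids) != values.shape[0]:
            raise DimensionMismatchError(
                f"{len(ids)} sample ids for {values.shape[0]} samples"
            )
        if len(set(ids)) != len(ids):
            raise InvalidInputError("sample ids must be unique")
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "EmbeddingMatrix":
        idx = np.asarray(indices, dtype=int)
        return EmbeddingMatrix(
            self.values[idx], tuple(self.sample_ids[i] for i in idx)
        )


@dataclass(frozen=True)
class LabelVector:
    """Binary class indicators in {0, 1}, aligned with an embedding's rows."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise InvalidInputError("labels must be 1-D")
        uniq = np.unique(labels)
        if not np.isin(uniq, [0, 1]).all():
            raise InvalidInputError(f"labels must be binary 0/1, got values {uniq}")
        object.__setattr__(self, "labels", labels.astype(int))

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices: Sequence[int]) -> "LabelVector":
        return LabelVector(self.labels[np.asarray(indices, dtype=int)])


@dataclass(frozen=True)
class GramMatrix:
    """An n x n matrix of kernel evaluations for one embedding.

    ``kernel_name`` identifies the producing kernel ("linear" or "rf"); RF
    Gram matrices additionally satisfy entries in [0, 1] with unit diagonal.
    """

    values: np.ndarray
    kernel_name: str
    sample_ids: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise InvalidInputError("Gram matrix must be square")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("Gram matrix contains non-finite entries")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise InvalidInputError("Gram matrix must be symmetric")
        object.__setattr__(self, "values", values)
        ids = self.sample_ids
        if ids is None:
            ids = tuple(range(values.shape[0]))
        object.__setattr__(self, "sample_ids", tuple(ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ForestParams:
    """Hyperparameters for the forest whose partitions define the RF kernel.

    Defaults follow standard random-forest practice: 100 trees, unrestricted
    depth, Gini impurity, sqrt(p) candidate features per split.
    """

    n_trees: int = 100
    max_depth: int | None = None
    criterion: str = "gini"
    max_features: str | int | float | None = "sqrt"
    min_samples_leaf: int = 1


@dataclass(frozen=True)
class TreeStructure:
    """Arrays describing one fitted binary decision tree.

    ``feature[i] < 0`` marks node ``i`` as a leaf; internal nodes carry the
    split feature index and threshold.  ``node_depth`` is 0 at the root.
    """

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    node_depth: np.ndarray

    @property
    def max_depth(self) -> int:
        return int(self.node_depth.max())

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def max_feature_index(self) -> int:
        internal = self.feature >= 0
        return int(self.feature[internal].max()) if internal.any() else -1


def _extract_tree(sk_tree) -> TreeStructure:
    t = sk_tree.tree_
    n_nodes = t.node_count
    depth = np.zeros(n_nodes, dtype=int)
    stack = [(0, 0)]
    while stack:
        node, d = stack.pop()
        depth[node] = d
        if t.children_left[node] != -1:
            stack.append((t.children_left[node], d + 1))
            stack.append((t.children_right[node], d + 1))
    return TreeStructure(
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        node_depth=depth,
    )


@dataclass(frozen=True)
class ForestPartitioner:
    """A fitted tree ensemble viewed as a distribution over data partitions.

    Wraps the fitted scikit-learn classifier (kept for predictions) and the
    extracted per-tree structures used for partition sampling and routing.
    """

    trees: tuple
    estimator: RandomForestClassifier = field(repr=False)
    seed: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def max_depths(self) -> np.ndarray:
        return np.array([t.max_depth for t in self.trees], dtype=int)

    def predict(self, X: EmbeddingMatrix) -> LabelVector:
        return LabelVector(self.estimator.predict(X.values))


@dataclass(frozen=True)
class PartitionAssignment:
    """One sampled partition: block membership of every sample under tree
    ``tree_index`` truncated at ``depth``."""

    tree_index: int
    depth: int
    block_ids: np.ndarray


# ---------------------------------------------------------------------------
# linear kernel
# ---------------------------------------------------------------------------


def linear_gram(X: EmbeddingMatrix) -> GramMatrix:
    """Dot-product Gram matrix K[i, j] = <x_i, x_j>.

    Positive semidefinite by construction; symmetrized to kill rounding
    asymmetry from the matrix product.
    """
    K = X.values @ X.values.T
    K = (K + K.T) / 2.0
    return GramMatrix(K, kernel_name="linear", sample_ids=X.sample_ids)


# ---------------------------------------------------------------------------
# forest fitting and partition machinery
# ---------------------------------------------------------------------------


def fit_forest(
    X: EmbeddingMatrix,
    y: LabelVector,
    params: ForestParams | None = None,
    seed: int = 0,
) -> ForestPartitioner:
    """Fit a random-forest classifier and expose its partition structure.

    Deterministic given (X, y, params, seed).  Tree induction is delegated to
    scikit-learn; only the fitted structures are consumed downstream.
    """
    params = params or ForestParams()
    if len(y) != X.n_samples:
        raise DimensionMismatchError(
            f"{len(y)} labels for {X.n_samples} samples"
        )
    if len(np.unique(y.labels)) < 2:
        raise DegenerateLabelsError(
            "forest fitting requires both classes present in the labels"
        )
    est = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        criterion=params.criterion,
        max_features=params.max_features,
        min_samples_leaf=params.min_samples_leaf,
        random_state=int(seed),
        n_jobs=1,
    )
    est.fit(X.values, y.labels)
    trees = tuple(_extract_tree(t) for t in est.estimators_)
    return ForestPartitioner(trees=trees, estimator=est, seed=int(seed))


def sample_partition(
    forest: ForestPartitioner, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw one (tree_index, depth) pair.

    The tree is uniform over the ensemble and the depth uniform over
    {0, ..., max_depth(tree)}; depth 0 is the root partition in which every
    sample shares a single block.
    """
    if forest.n_trees < 1:
        raise InvalidModelError("cannot sample partitions from an empty forest")
    tree_index = int(rng.integers(forest.n_trees))
    depth = int(rng.integers(forest.trees[tree_index].max_depth + 1))
    return tree_index, depth


def _route(tree: TreeStructure, X: np.ndarray, depth: int) -> np.ndarray:
    """Route samples down ``tree``, stopping at ``depth`` or at a leaf.

    Returns the node id at which each sample stops; equal ids mean same block.
    Samples resting in a leaf shallower than ``depth`` keep that leaf as their
    block — a partition must assign every sample to exactly one block.
    """
    n = X.shape[0]
    node = np.zeros(n, dtype=np.intp)
    for _ in range(depth):
        feat = tree.feature[node]
        active = feat >= 0
        if not active.any():
            break
        idx = np.flatnonzero(active)
        f = feat[idx]
        left = X[idx, f] <= tree.threshold[node[idx]]
        node[idx] = np.where(
            left, tree.children_left[node[idx]], tree.children_right[node[idx]]
        )
    return node


def block_ids(
    forest: ForestPartitioner,
    tree_index: int,
    depth: int,
    X: EmbeddingMatrix,
) -> PartitionAssignment:
    """Assign every sample of X to its block under one (tree, depth) partition."""
    if not 0 <= tree_index < forest.n_trees:
        raise InvalidModelError(f"tree index {tree_index} out of range")
    tree = forest.trees[tree_index]
    if not 0 <= depth <= tree.max_depth:
        raise InvalidParameterError(
            f"depth {depth} outside [0, {tree.max_depth}] for tree {tree_index}"
        )
    if tree.max_feature_index() >= X.n_features:
        raise DimensionMismatchError(
            f"tree splits on feature {tree.max_feature_index()} but embedding "
            f"has only {X.n_features} features"
        )
    blocks = _route(tree, X.values, depth)
    return PartitionAssignment(tree_index=tree_index, depth=depth, block_ids=blocks)


def _co_membership(blocks: np.ndarray) -> np.ndarray:
    return (blocks[:, None] == blocks[None, :]).astype(float)


def rf_gram(
    forest: ForestPartitioner,
    X: EmbeddingMatrix,
    n_partitions: int = 500,
    rng: np.random.Generator | int | None = None,
) -> GramMatrix:
    """Monte-Carlo estimate of the RF partition kernel Gram matrix.

    Entry (i, j) is the fraction of the ``n_partitions`` sampled (tree, depth)
    partitions in which samples i and j share a block.  The diagonal is exactly
    1 (a sample always shares its own block) and all entries lie in [0, 1].
    Identical draws are aggregated so each distinct partition is routed once.
    """
    if n_partitions < 1:
        raise InvalidParameterError("n_partitions must be >= 1")
    if forest.n_trees < 1:
        raise InvalidModelError("cannot build an RF Gram from an empty forest")
    rng = np.random.default_rng(rng)
    draws = [sample_partition(forest, rng) for _ in range(n_partitions)]
    counts: dict[tuple[int, int], int] = {}
    for d in draws:
        counts[d] = counts.get(d, 0) + 1
    K = np.zeros((X.n_samples, X.n_samples))
    for (tree_index, depth), count in counts.items():
        assignment = block_ids(forest, tree_index, depth, X)
        K += count * _co_membership(assignment.block_ids)
    K /= n_partitions
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return GramMatrix(K, kernel_name="rf", sample_ids=X.sample_ids)


def exact_rf_gram(
    forest: ForestPartitioner,
    X: EmbeddingMatrix,
    max_enumerations: int = 10_000,
) -> GramMatrix:
    """Exact expectation of the RF partition kernel under the sampling scheme.

    Averages the shared-block indicator over every depth of every tree:
    mean over trees t of the mean over depths d in {0..max_depth(t)}.  This is
    the quantity :func:`rf_gram` estimates, and serves as its oracle in tests.
    """
    if forest.n_trees < 1:
        raise InvalidModelError("cannot build an RF Gram from an empty forest")
    total = int((forest.max_depths + 1).sum())
    if total > max_enumerations:
        raise ComplexityCapError(
            f"{total} (tree, depth) pairs exceed the enumeration cap "
            f"of {max_enumerations}"
        )
    K = np.zeros((X.n_samples, X.n_samples))
    for tree_index, tree in enumerate(forest.trees):
        per_tree = np.zeros_like(K)
        for depth in range(tree.max_depth + 1):
            assignment = block_ids(forest, tree_index, depth, X)
            per_tree += _co_membership(assignment.block_ids)
        K += per_tree / (tree.max_depth + 1)
    K /= forest.n_trees
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return GramMatrix(K, kernel_name="rf", sample_ids=X.sample_ids)
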