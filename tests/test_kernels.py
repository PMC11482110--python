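"""Linear and RF partition kernels: Gram construction and its sampling oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfcka import EmbeddingMatrix, ForestParams, LabelVector
from rfcka.errors import (
    ComplexityCapError,
    DegenerateLabelsError,
    DimensionMismatchError,
    InvalidInputError,
    InvalidModelError,
    InvalidParameterError,
)
from rfcka.kernels import (
    block_ids,
    exact_rf_gram,
    fit_forest,
    linear_gram,
    rf_gram,
    sample_partition,
)

from conftest import random_small_forest


class TestLinearGram:
    @pytest.mark.parametrize(
        "X, expected",
        [
            (np.eye(2), np.eye(2)),
            (np.array([[1.0], [2.0]]), np.array([[1.0, 2.0], [2.0, 4.0]])),
        ],
    )
    def test_dot_products(self, X, expected):
        K = linear_gram(EmbeddingMatrix(X))
        np.testing.assert_allclose(K.values, expected)

    def test_scaling_is_quadratic(self, gaussian_embedding):
        K = linear_gram(gaussian_embedding)
        K3 = linear_gram(EmbeddingMatrix(3.0 * gaussian_embedding.values))
        np.testing.assert_allclose(K3.values, 9.0 * K.values, rtol=1e-12)

    def test_psd(self, gaussian_embedding):
        K = linear_gram(gaussian_embedding)
        eigs = np.linalg.eigvalsh(K.values)
        assert eigs.min() >= -1e-8 * np.trace(K.values)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            EmbeddingMatrix(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestFitForest:
    def test_separable_stump_threshold_in_gap(self, stump_forest):
        forest, _, _ = stump_forest
        tree = forest.trees[0]
        internal = np.flatnonzero(tree.feature >= 0)
        assert len(internal) == 1  # a single split suffices
        assert -1.0 < tree.threshold[internal[0]] < 1.0

    def test_deterministic_given_seed(self, stump_forest):
        _, X, y = stump_forest
        a = fit_forest(X, y, ForestParams(n_trees=5), seed=7)
        b = fit_forest(X, y, ForestParams(n_trees=5), seed=7)
        for ta, tb in zip(a.trees, b.trees):
            np.testing.assert_array_equal(ta.feature, tb.feature)
            np.testing.assert_array_equal(ta.threshold, tb.threshold)

    def test_seeds_change_structure(self, rng):
        X = EmbeddingMatrix(rng.standard_normal((60, 5)))
        y = LabelVector((rng.random(60) < 0.5).astype(int))
        a = fit_forest(X, y, ForestParams(n_trees=5), seed=0)
        b = fit_forest(X, y, ForestParams(n_trees=5), seed=1)
        serial = lambda f: [
            (t.feature.tolist(), t.threshold.tolist()) for t in f.trees
        ]
        assert serial(a) != serial(b)

    def test_single_class_rejected(self, rng):
        X = EmbeddingMatrix(rng.standard_normal((10, 2)))
        with pytest.raises(DegenerateLabelsError):
            fit_forest(X, LabelVector(np.ones(10, dtype=int)))


class TestSamplePartition:
    def test_depth_zero_forest_single_outcome(self, rng):
        X = EmbeddingMatrix(rng.standard_normal((10, 2)))
        y = LabelVector(np.array([0, 1] * 5))
        # min_samples_leaf = n prevents any split: a single root-leaf tree
        forest = fit_forest(X, y, ForestParams(n_trees=1, min_samples_leaf=10))
        draws = {sample_partition(forest, rng) for _ in range(50)}
        assert draws == {(0, 0)}

    def test_depth_frequencies_uniform(self, rng):
        forest, _ = random_small_forest(0, n=60, n_trees=1, max_depth=3)
        assert forest.trees[0].max_depth == 3
        n_draws = 40_000
        depths = np.array(
            [sample_partition(forest, rng)[1] for _ in range(n_draws)]
        )
        sigma = np.sqrt(0.25 * 0.75 / n_draws)
        for d in range(4):
            assert abs(np.mean(depths == d) - 0.25) < 3 * sigma + 1e-12

    def test_tree_frequencies_uniform(self, rng):
        forest, _ = random_small_forest(1, n=40, n_trees=2, max_depth=2)
        n_draws = 40_000
        trees = np.array(
            [sample_partition(forest, rng)[0] for _ in range(n_draws)]
        )
        sigma = np.sqrt(0.25 / n_draws)
        assert abs(np.mean(trees == 0) - 0.5) < 3 * sigma


class TestBlockIds:
    def test_depth_zero_single_block(self, stump_forest):
        forest, X, _ = stump_forest
        assignment = block_ids(forest, 0, 0, X)
        assert len(np.unique(assignment.block_ids)) == 1

    def test_single_split_separates_sides(self, stump_forest):
        forest, X, _ = stump_forest
        blocks = block_ids(forest, 0, 1, X).block_ids
        assert blocks[0] == blocks[1]
        assert blocks[2] == blocks[3]
        assert blocks[0] != blocks[2]

    def test_shallow_leaf_keeps_its_block(self):
        # three clusters: one split isolates the left cluster as a depth-1
        # leaf, the right side needs a second split
        X = EmbeddingMatrix(
            np.array([[-5.0], [-4.5], [1.0], [1.5], [5.0], [5.5]])
        )
        y = LabelVector(np.array([0, 0, 1, 1, 0, 0]))
        forest = fit_forest(
            X, y, ForestParams(n_trees=1, max_features=None), seed=0
        )
        tree = forest.trees[0]
        max_d = tree.max_depth
        assert max_d >= 2
        shallow = block_ids(forest, 0, 1, X).block_ids
        deep = block_ids(forest, 0, max_d, X).block_ids
        # samples whose leaf is shallower than max_d keep that leaf's block
        leaf_depth = tree.node_depth[deep]
        for i in np.flatnonzero(leaf_depth < max_d):
            assert deep[i] in deep  # block id is the leaf itself
        # a sample in a depth-1 leaf has the same block at depth 1 and max_d
        d1_leaves = np.flatnonzero(leaf_depth == 1)
        if len(d1_leaves):
            np.testing.assert_array_equal(shallow[d1_leaves], deep[d1_leaves])

    def test_feature_out_of_range(self, rng):
        forest, _ = random_small_forest(2)
        X_small = EmbeddingMatrix(rng.standard_normal((5, 1)))
        with pytest.raises(DimensionMismatchError):
            block_ids(forest, 0, 1, X_small)


class TestRfGram:
    def test_depth_zero_forest_all_ones(self, rng):
        X = EmbeddingMatrix(rng.standard_normal((8, 2)))
        y = LabelVector(np.array([0, 1] * 4))
        forest = fit_forest(X, y, ForestParams(n_trees=2, min_samples_leaf=8))
        K = rf_gram(forest, X, 50, rng)
        np.testing.assert_array_equal(K.values, np.ones((8, 8)))
        Ke = exact_rf_gram(forest, X)
        np.testing.assert_array_equal(Ke.values, np.ones((8, 8)))

    def test_single_split_exact_values(self, stump_forest):
        forest, X, _ = stump_forest
        expected = np.array(
            [
                [1.0, 1.0, 0.5, 0.5],
                [1.0, 1.0, 0.5, 0.5],
                [0.5, 0.5, 1.0, 1.0],
                [0.5, 0.5, 1.0, 1.0],
            ]
        )
        np.testing.assert_allclose(exact_rf_gram(forest, X).values, expected)

    def test_invariants(self, rng):
        forest, X = random_small_forest(3)
        K = rf_gram(forest, X, 200, rng).values
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(K), np.ones(X.n_samples))
        assert K.min() >= 0.0 and K.max() <= 1.0

    def test_sampled_close_to_exact(self, rng):
        forest, X = random_small_forest(4)
        Ke = exact_rf_gram(forest, X).values
        Ks = rf_gram(forest, X, 2000, rng).values
        assert np.abs(Ks - Ke).max() <= 3 * np.sqrt(0.25 / 2000)

    def test_lln_convergence(self, stump_forest):
        forest, X, _ = stump_forest
        Ke = exact_rf_gram(forest, X).values
        Ks = rf_gram(forest, X, 50_000, np.random.default_rng(0)).values
        assert np.abs(Ks - Ke).max() <= 0.01

    def test_merged_samples_share_kernel_one(self):
        X = EmbeddingMatrix(np.array([[-2.0], [-2.0], [1.0], [2.0]]))
        y = LabelVector(np.array([0, 0, 1, 1]))
        forest = fit_forest(X, y, ForestParams(n_trees=3, max_features=None))
        K = exact_rf_gram(forest, X).values
        assert K[0, 1] == 1.0  # identical feature vectors always share a block

    def test_invalid_partition_count(self, stump_forest):
        forest, X, _ = stump_forest
        with pytest.raises(InvalidParameterError):
            rf_gram(forest, X, 0, np.random.default_rng(0))

    def test_enumeration_cap(self, stump_forest):
        forest, X, _ = stump_forest
        with pytest.raises(ComplexityCapError):
            exact_rf_gram(forest, X, max_enumerations=1)

    def test_empty_forest_rejected(self, stump_forest):
        _, X, _ = stump_forest
        from rfcka.kernels import ForestPartitioner

        empty = ForestPartitioner(trees=(), estimator=None)
        with pytest.raises(InvalidModelError):
            rf_gram(empty, X, 10, np.random.default_rng(0))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rf_gram_invariants_property(seed):
    """RF Gram invariants hold for arbitrary small forests and sample sets."""
    forest, X = random_small_forest(seed, n=15, n_trees=2, max_depth=3)
    K = rf_gram(forest, X, 37, np.random.default_rng(seed)).values
    assert np.allclose(K, K.T)
    assert np.all(np.diag(K) == 1.0)
    assert K.min() >= 0.0 and K.max() <= 1.0
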