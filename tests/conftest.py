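import numpy as np
import pytest

from rfcka import EmbeddingMatrix, ForestParams, LabelVector, fit_forest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_embedding(rng):
    return EmbeddingMatrix(rng.standard_normal((50, 10)))


@pytest.fixture
def stump_forest():
    """One tree, one clean split at x=0: the smallest non-trivial partitioner."""
    X = EmbeddingMatrix(np.array([[-2.0], [-1.0], [1.0], [2.0]]))
    y = LabelVector(np.array([0, 0, 1, 1]))
    forest = fit_forest(X, y, ForestParams(n_trees=1, max_features=None), seed=0)
    return forest, X, y


def random_small_forest(seed, n=30, n_trees=3, max_depth=3):
    """A small forest on noisy 2-class data, for oracle-equivalence trials."""
    gen = np.random.default_rng(seed)
    X = EmbeddingMatrix(gen.standard_normal((n, 4)))
    y = LabelVector((X.values[:, 0] + 0.5 * gen.standard_normal(n) > 0).astype(int))
    params = ForestParams(n_trees=n_trees, max_depth=max_depth)
    return fit_forest(X, y, params, seed=seed), X
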