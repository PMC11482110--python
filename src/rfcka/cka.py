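"""Centered kernel alignment (CKA) and the empirical HSIC estimator.

CKA compares two representations of the same n samples through their Gram
matrices K and L:

    CKA(K, L) = HSIC(K, L) / sqrt(HSIC(K, K) * HSIC(L, L))

with the empirical Hilbert-Schmidt independence criterion

    HSIC(K, L) = trace(K H L H) / (n - 1)^2,     H = I - (1/n) 1 1^T.

The (n-1)^2 denominator is the biased-but-consistent estimator; the
normalization makes CKA invariant to isotropic scaling of either kernel.
For PSD Grams CKA lies in [0, 1]: 1 means strongly dependent representations,
0 means independent.

``cka_rf`` is the end-to-end procedure for random forests: fit one forest per
embedding on the shared labels, build each forest's sampled partition-kernel
Gram, and align them.  Sampled RF Grams are not exactly PSD, so the raw ratio
can fall slightly outside [0, 1] by sampling noise; the reported ``cka`` is
clipped to the interval while ``cka_raw`` keeps the diagnostic value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateRepresentationError,
    DimensionMismatchError,
    InvalidParameterError,
)
from .kernels import (
    EmbeddingMatrix,
    ForestParams,
    GramMatrix,
    LabelVector,
    fit_forest,
    linear_gram,
    rf_gram,
)

__all__ = [
    "CenteringMatrix",
    "ComparisonResult",
    "centering_matrix",
    "hsic",
    "cka",
    "cka_linear",
    "cka_rf",
]

# relative floor below which a self-HSIC is treated as degenerate (constant Gram)
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class CenteringMatrix:
    """H_n = I - (1/n) * ones(n, n): projects out the constant component."""

    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("centering matrix requires n >= 2")


def centering_matrix(n: int) -> CenteringMatrix:
    """The order-n centering matrix; idempotent with row sums 0 and trace n-1."""
    if n < 2:
        raise InvalidParameterError("centering matrix requires n >= 2")
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    return CenteringMatrix(n=n, values=H)


def _center(K: np.ndarray) -> np.ndarray:
    # H K H via row/column mean subtraction (O(n^2), no explicit H)
    row = K.mean(axis=0, keepdims=True)
    col = K.mean(axis=1, keepdims=True)
    return K - row - col + K.mean()


def hsic(K: GramMatrix, L: GramMatrix) -> float:
    """Empirical HSIC: trace(K H L H) / (n - 1)^2.

    Zero when either Gram is constant (centering annihilates it);
    non-negative when both Grams are PSD.
    """
    if K.n != L.n:
        raise DimensionMismatchError(
            f"Gram orders differ: {K.n} vs {L.n}"
        )
    n = K.n
    if n < 2:
        raise InvalidParameterError("HSIC requires n >= 2")
    Kc = _center(K.values)
    return float(np.sum(Kc * L.values) / (n - 1) ** 2)


def _self_hsic_floor(K: GramMatrix) -> float:
    scale = max(1.0, float(np.abs(K.values).max()))
    return _DEGENERATE_RTOL * scale * scale


def cka(K: GramMatrix, L: GramMatrix, clip: bool = True) -> float:
    """CKA of two Gram matrices; symmetric in its arguments.

    Raises :class:`DegenerateRepresentationError` when either Gram is
    (numerically) constant — a silent 0 would masquerade as independence.
    """
    hxx = hsic(K, K)
    hyy = hsic(L, L)
    if hxx <= _self_hsic_floor(K) or hyy <= _self_hsic_floor(L):
        raise DegenerateRepresentationError(
            "constant Gram matrix: self-HSIC is zero, CKA undefined"
        )
    value = hsic(K, L) / np.sqrt(hxx * hyy)
    if clip:
        value = float(np.clip(value, 0.0, 1.0))
    return float(value)


@dataclass(frozen=True)
class ComparisonResult:
    """One CKA value with the provenance needed to reproduce it.

    ``cka`` is clipped to [0, 1]; ``cka_raw`` is the unclipped ratio
    hsic_xy / sqrt(hsic_xx * hsic_yy), which sampling noise in RF Grams can
    push marginally outside the interval.
    """

    cka: float
    cka_raw: float
    kernel_name: str
    hsic_xy: float
    hsic_xx: float
    hsic_yy: float
    n_samples: int
    n_partitions: int | None = None
    forest_seeds: tuple[int, int] | None = None
    partition_seed: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["forest_seeds"] is not None:
            d["forest_seeds"] = list(d["forest_seeds"])
        return d


def _compare(K: GramMatrix, L: GramMatrix, **provenance) -> ComparisonResult:
    hxx = hsic(K, K)
    hyy = hsic(L, L)
    if hxx <= _self_hsic_floor(K) or hyy <= _self_hsic_floor(L):
        raise DegenerateRepresentationError(
            "constant Gram matrix: self-HSIC is zero, CKA undefined"
        )
    hxy = hsic(K, L)
    raw = hxy / np.sqrt(hxx * hyy)
    return ComparisonResult(
        cka=float(np.clip(raw, 0.0, 1.0)),
        cka_raw=float(raw),
        kernel_name=K.kernel_name,
        hsic_xy=hxy,
        hsic_xx=hxx,
        hsic_yy=hyy,
        n_samples=K.n,
        **provenance,
    )


def _check_aligned(X: EmbeddingMatrix, Y: EmbeddingMatrix) -> None:
    if X.sample_ids != Y.sample_ids:
        raise AlignmentError(
            "embeddings must share sample ids in identical order"
        )


def cka_linear(X: EmbeddingMatrix, Y: EmbeddingMatrix) -> ComparisonResult:
    """Linear-kernel CKA of two embeddings of the same samples.

    Invariant to orthogonal transformation of either embedding (the dot
    product kernel) and to isotropic scaling (the normalization).
    """
    _check_aligned(X, Y)
    return _compare(linear_gram(X), linear_gram(Y))


def cka_rf(
    X1: EmbeddingMatrix,
    X2: EmbeddingMatrix,
    y: LabelVector,
    params: ForestParams | None = None,
    n_partitions: int = 500,
    forest_seeds: tuple[int, int] = (0, 1),
    partition_seed: int = 0,
    gram_samples: tuple[EmbeddingMatrix, EmbeddingMatrix] | None = None,
) -> ComparisonResult:
    """RF-kernel CKA: fit one forest per embedding, align their partition kernels.

    Each forest is fitted on (X_i, y) with its own seed; each Gram is a
    Monte-Carlo estimate from ``n_partitions`` sampled (tree, depth)
    partitions.  Two independent RNG streams are derived from
    ``partition_seed`` so the two samplings do not interact.

    ``gram_samples`` optionally supplies the evaluation embeddings on which
    the Grams are computed (e.g. a held-out test set) while the forests are
    fitted on (X1, X2); by default the fitting samples are reused.
    """
    if n_partitions < 1:
        raise InvalidParameterError("n_partitions must be >= 1")
    _check_aligned(X1, X2)
    forest1 = fit_forest(X1, y, params=params, seed=forest_seeds[0])
    forest2 = fit_forest(X2, y, params=params, seed=forest_seeds[1])
    E1, E2 = gram_samples if gram_samples is not None else (X1, X2)
    _check_aligned(E1, E2)
    stream1, stream2 = np.random.SeedSequence(partition_seed).spawn(2)
    K = rf_gram(forest1, E1, n_partitions, np.random.default_rng(stream1))
    L = rf_gram(forest2, E2, n_partitions, np.random.default_rng(stream2))
    return _compare(
        K,
        L,
        n_partitions=n_partitions,
        forest_seeds=(int(forest_seeds[0]), int(forest_seeds[1])),
        partition_seed=int(partition_seed),
    )
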