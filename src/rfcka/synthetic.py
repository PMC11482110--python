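"""Seeded generators for every synthetic input the package's validation needs.

Three families:

* 2-D Gaussian blob classification data, the classic fixture for showing that
  axis-aligned learners break under rotation while linear ones do not;
* fingerprint-like binary matrices of independent Bernoulli bits, emulating
  the binary, sparse character of circular fingerprints;
* correlated embedding pairs in which a latent signal determines the labels
  and a mixing weight rho in [0, 1] controls how much of that signal the
  second embedding shares — rho = 0 gives an independent embedding, rho = 1
  a copy, and the intermediate values a graded-similarity family on which
  embedding similarity and prediction agreement can be correlated.

Every generator is a pure function of its arguments: the global seed fans out
into named substreams per generator, so identical calls replay bit-identically
and adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib

import numpy as np

from .errors import InvalidParameterError
from .kernels import EmbeddingMatrix, LabelVector
from .rotation import LabelledDataset

__all__ = [
    "make_blobs_2d",
    "make_fingerprint_like",
    "make_correlated_pair",
    "make_rho_family",
]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream: the same (seed, name) always yields the same stream."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def make_blobs_2d(n: int, separation: float = 4.0, seed: int = 0) -> LabelledDataset:
    """Two balanced isotropic Gaussian classes in the plane.

    Class centers sit at +-(separation/2, 0) along the first axis with unit
    class-conditional variance, so ``separation`` is the center distance in
    units of the noise standard deviation.
    """
    if n < 4 or n % 2 != 0:
        raise InvalidParameterError("n must be even and >= 4")
    rng = _stream(seed, "blobs_2d")
    half = n // 2
    offset = np.array([separation / 2.0, 0.0])
    X = np.vstack(
        [
            rng.standard_normal((half, 2)) - offset,
            rng.standard_normal((half, 2)) + offset,
        ]
    )
    y = np.concatenate([np.zeros(half, dtype=int), np.ones(half, dtype=int)])
    perm = rng.permutation(n)
    return LabelledDataset(EmbeddingMatrix(X[perm]), LabelVector(y[perm]))


def make_fingerprint_like(
    n: int, p: int, density: float = 0.1, seed: int = 0
) -> EmbeddingMatrix:
    """Independent Bernoulli(density) bits: a fingerprint-shaped binary matrix."""
    if not 0.0 < density < 1.0:
        raise InvalidParameterError("density must lie strictly between 0 and 1")
    rng = _stream(seed, "fingerprint_like")
    bits = (rng.random((n, p)) < density).astype(float)
    return EmbeddingMatrix(bits)


# latent dimensionality and noise scale of the correlated-pair family; the
# signal loadings are orthonormal so signal and noise variances are comparable
_LATENT_DIM = 4
_NOISE_SD = 0.5


def make_correlated_pair(
    n: int,
    p1: int,
    p2: int,
    rho: float,
    seed: int = 0,
) -> tuple[EmbeddingMatrix, EmbeddingMatrix, LabelVector]:
    """Two embeddings sharing a tunable fraction of a label-bearing signal.

    A latent Gaussian signal z (n x 4) determines the labels through a fixed
    linear rule.  Embedding 1 is the signal mapped through an orthonormal
    loading plus Gaussian noise.  Embedding 2 mixes a rotated copy of the
    signal features with independent noise:

        X2 = rho * (z A2) + (1 - rho) * noise,

    where A2 is a second orthonormal loading (a rotated image of the same
    latent signal).  rho = 0 makes the embeddings independent; rho = 1 with
    p1 == p2 takes the degenerate branch X2 = X1 exactly.

    The latent signal, labels, loadings, and noise draws depend only on
    (n, p1, p2, seed), so varying rho alone yields a family of embeddings of
    the *same* samples with graded shared information.
    """
    if not 0.0 <= rho <= 1.0:
        raise InvalidParameterError("rho must lie in [0, 1]")
    if min(p1, p2) < _LATENT_DIM:
        raise InvalidParameterError(
            f"embedding dimensions must be >= {_LATENT_DIM}"
        )
    rng = _stream(seed, "correlated_pair")
    k = _LATENT_DIM
    z = rng.standard_normal((n, k))
    w = rng.standard_normal(k)
    y = (z @ w > 0).astype(int)

    def orthonormal_loading(p: int) -> np.ndarray:
        Q, R = np.linalg.qr(rng.standard_normal((p, k)))
        return (Q * np.sign(np.diag(R))).T  # k x p, orthonormal rows

    A1 = orthonormal_loading(p1)
    A2 = orthonormal_loading(p2)
    X1 = z @ A1 + _NOISE_SD * rng.standard_normal((n, p1))
    noise2 = rng.standard_normal((n, p2))
    if rho == 1.0 and p1 == p2:
        X2 = X1.copy()
    else:
        X2 = rho * (z @ A2) + (1.0 - rho) * noise2
    ids = tuple(range(n))
    return (
        EmbeddingMatrix(X1, ids),
        EmbeddingMatrix(X2, ids),
        LabelVector(y),
    )


def make_rho_family(
    n: int,
    p: int,
    rhos: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
) -> tuple[list[EmbeddingMatrix], LabelVector]:
    """A family of embeddings of the same samples with graded shared signal.

    Calls :func:`make_correlated_pair` once per rho with the same seed: the
    latent signal, labels and noise are identical across calls, so only the
    mixing weight differs.  Returns the rho-indexed second embeddings and the
    shared labels — a self-contained stand-in for a set of featurization
    strategies of increasing mutual similarity.
    """
    embeddings = []
    labels = None
    for rho in rhos:
        _, X2, y = make_correlated_pair(n, p, p, rho, seed=seed)
        embeddings.append(X2)
        labels = y
    return embeddings, labels
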