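"""File-driven orchestration: featurize molecules, run pairwise CKA across
embedding strategies and seeds, and correlate embedding similarity with
prediction agreement.

The experimental protocol mirrors the standard design for comparing
featurization strategies: a single stratified train/test split is fixed per
run and reused for every strategy and every seed (otherwise different samples
would be compared and CKA would collapse toward 0), one forest is trained per
(strategy, seed), Gram matrices are computed on the test partition by default,
and cross-seed self-similarity — CKA between two forests of the same strategy
differing only in seed — is reported on the diagonal of similarity matrices as
the reference value for "high" similarity, rather than the trivial constant 1.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .cka import cka
from .errors import (
    AlignmentError,
    EmptyInputError,
    InsufficientDataError,
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
from .metrics import mcc_inter

logger = logging.getLogger(__name__)

__all__ = [
    "FeaturizationSpec",
    "SimilarityMatrixReport",
    "CorrelationReport",
    "featurize_smiles",
    "pairwise_matrix",
    "correlate_similarity_agreement",
]


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeaturizationSpec:
    """Circular (Morgan) fingerprint configuration.

    ``radius`` is the bond radius of the hashed atom environments; radii 1-10
    are supported.  ``n_bits`` is the folded bit-vector length.
    """

    method: str = "circular"
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.method != "circular":
            raise InvalidParameterError(f"unsupported method {self.method!r}")
        if not 1 <= self.radius <= 10:
            raise InvalidParameterError("radius must be in 1..10")
        if self.n_bits < 8:
            raise InvalidParameterError("n_bits must be >= 8")


def featurize_smiles(
    records: list[tuple[str, str]], spec: FeaturizationSpec
) -> EmbeddingMatrix:
    """Hash SMILES records into circular fingerprints.

    ``records`` are (id, smiles) pairs (see :func:`rfcka.io.read_smiles`).
    Hashing is delegated to RDKit's Morgan generator.  Unparseable records are
    skipped and reported through the module logger with a count; if nothing
    parses an :class:`EmptyInputError` is raised.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=spec.radius, fpSize=spec.n_bits
    )
    rows, ids, skipped = [], [], 0
    for rec_id, smi in records:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            skipped += 1
            logger.warning("skipping unparseable SMILES %r (id %s)", smi, rec_id)
            continue
        fp = gen.GetFingerprintAsNumPy(mol)
        rows.append(np.asarray(fp, dtype=float))
        ids.append(rec_id)
    if skipped:
        logger.warning("%d of %d SMILES records skipped", skipped, len(records))
    if not rows:
        raise EmptyInputError("no parseable SMILES records")
    return EmbeddingMatrix(np.vstack(rows), tuple(ids))


# ---------------------------------------------------------------------------
# shared experiment machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _RunConfig:
    kernel: str
    n_seeds: int
    params: ForestParams
    n_partitions: int
    split_fraction: float
    gram_on: str
    seed: int


def _check_alignment(embeddings: list[EmbeddingMatrix]) -> None:
    ids = embeddings[0].sample_ids
    for e in embeddings[1:]:
        if e.sample_ids != ids:
            raise AlignmentError("all embeddings must share sample ids in order")


def _derive_seed(base: int, *key: int) -> int:
    # sklearn wants a seed below 2**32; keep below 2**31 for portability
    ss = np.random.SeedSequence(int(base), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def _split_indices(
    y: LabelVector, split_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx,
        train_size=split_fraction,
        stratify=y.labels,
        random_state=_derive_seed(seed, 0xF17),
    )
    return np.sort(train), np.sort(test)


def _fit_models(
    embeddings: list[EmbeddingMatrix],
    y: LabelVector,
    cfg: _RunConfig,
) -> tuple[dict, dict, np.ndarray, np.ndarray]:
    """Fit one forest per (embedding, seed); build one Gram per model.

    Returns (grams, predictions, train_idx, test_idx).  For the linear kernel
    the Gram depends only on the embedding, so it is shared across seeds;
    forests (and hence predictions) are still fitted per seed.
    """
    train_idx, test_idx = _split_indices(y, cfg.split_fraction, cfg.seed)
    eval_idx = {"test": test_idx, "train": train_idx,
                "all": np.arange(len(y))}[cfg.gram_on]
    y_train = y.subset(train_idx)
    grams: dict[tuple[int, int], GramMatrix] = {}
    preds: dict[tuple[int, int], np.ndarray] = {}
    for e, X in enumerate(embeddings):
        X_train = X.subset(train_idx)
        X_eval = X.subset(eval_idx)
        X_test = X.subset(test_idx)
        linear_K = linear_gram(X_eval) if cfg.kernel == "linear" else None
        for s in range(cfg.n_seeds):
            forest = fit_forest(
                X_train, y_train, params=cfg.params,
                seed=_derive_seed(cfg.seed, 1, e, s),
            )
            preds[(e, s)] = forest.predict(X_test).labels
            if cfg.kernel == "rf":
                rng = np.random.default_rng(_derive_seed(cfg.seed, 2, e, s))
                grams[(e, s)] = rf_gram(forest, X_eval, cfg.n_partitions, rng)
            else:
                grams[(e, s)] = linear_K
    return grams, preds, train_idx, test_idx


# ---------------------------------------------------------------------------
# pairwise similarity matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityMatrixReport:
    """Mean and standard deviation of CKA per strategy pair across seeds.

    Diagonal entries record cross-seed self-similarity (CKA between two seeds
    of the same strategy) rather than the constant 1, because that is the
    reference baseline against which off-diagonal similarity is judged.  For
    the deterministic linear kernel the diagonal is exactly 1.
    """

    names: tuple
    kernel_name: str
    n_seeds: int
    mean: np.ndarray
    sd: np.ndarray
    n_partitions: int | None = None
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean, index=list(self.names),
                            columns=list(self.names))

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "kernel_name": self.kernel_name,
            "n_seeds": self.n_seeds,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n_partitions": self.n_partitions,
            "seed": self.seed,
        }


def pairwise_matrix(
    embeddings: list[EmbeddingMatrix],
    y: LabelVector,
    kernel: str = "rf",
    n_seeds: int = 5,
    names: list[str] | None = None,
    params: ForestParams | None = None,
    n_partitions: int = 500,
    split_fraction: float = 0.8,
    gram_on: str = "test",
    seed: int = 0,
) -> SimilarityMatrixReport:
    """Average CKA between every pair of embedding strategies across seeds.

    For the RF kernel, every (strategy, seed) model contributes one Gram and
    each strategy pair is averaged over all seed combinations (distinct-seed
    pairs on the diagonal).  The identical train/test split is reused across
    seeds and strategies so comparisons are over the same samples.
    """
    if kernel not in ("linear", "rf"):
        raise InvalidParameterError(f"unknown kernel {kernel!r}")
    _check_alignment(embeddings)
    m = len(embeddings)
    names = tuple(names) if names else tuple(f"E{i}" for i in range(m))
    cfg = _RunConfig(kernel, n_seeds, params or ForestParams(),
                     n_partitions, split_fraction, gram_on, seed)
    grams, _, _, _ = _fit_models(embeddings, y, cfg)

    mean = np.full((m, m), np.nan)
    sd = np.full((m, m), np.nan)
    for a in range(m):
        for b in range(a, m):
            if kernel == "linear":
                values = [1.0] if a == b else [cka(grams[(a, 0)], grams[(b, 0)])]
            elif a == b:
                values = [
                    cka(grams[(a, s)], grams[(a, t)])
                    for s, t in itertools.combinations(range(n_seeds), 2)
                ]
            else:
                values = [
                    cka(grams[(a, s)], grams[(b, t)])
                    for s in range(n_seeds)
                    for t in range(n_seeds)
                ]
            if values:
                mean[a, b] = mean[b, a] = float(np.mean(values))
                sd[a, b] = sd[b, a] = float(np.std(values))
    return SimilarityMatrixReport(
        names=names, kernel_name=kernel, n_seeds=n_seeds, mean=mean, sd=sd,
        n_partitions=n_partitions if kernel == "rf" else None, seed=seed,
    )


# ---------------------------------------------------------------------------
# similarity vs prediction agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation between embedding similarity (CKA) and prediction
    agreement (inter-model MCC) over all unordered model pairs.

    ``degenerate`` flags zero variance in either quantity (e.g. all models
    identical), in which case r and p are NaN.
    """

    r: float
    p: float
    pairs: pd.DataFrame = field(repr=False)
    kernel_name: str = "rf"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "r": None if np.isnan(self.r) else self.r,
            "p": None if np.isnan(self.p) else self.p,
            "kernel_name": self.kernel_name,
            "degenerate": self.degenerate,
            "n_pairs": int(len(self.pairs)),
        }


def correlate_similarity_agreement(
    embeddings: list[EmbeddingMatrix],
    y: LabelVector,
    kernel: str = "rf",
    n_seeds: int = 4,
    names: list[str] | None = None,
    params: ForestParams | None = None,
    n_partitions: int = 500,
    split_fraction: float = 0.8,
    gram_on: str = "test",
    seed: int = 0,
) -> CorrelationReport:
    """Correlate CKA with inter-model MCC across all unordered model pairs.

    One forest is trained per (embedding, seed); for every unordered pair of
    distinct models the CKA of their Grams and the MCC between their held-out
    predictions are collected, and Pearson r with its p value is computed over
    the pair table (delegated to scipy).
    """
    if kernel not in ("linear", "rf"):
        raise InvalidParameterError(f"unknown kernel {kernel!r}")
    _check_alignment(embeddings)
    m = len(embeddings)
    names = tuple(names) if names else tuple(f"E{i}" for i in range(m))
    cfg = _RunConfig(kernel, n_seeds, params or ForestParams(),
                     n_partitions, split_fraction, gram_on, seed)
    grams, preds, _, _ = _fit_models(embeddings, y, cfg)

    models = sorted(grams.keys())
    rows = []
    for (ea, sa), (eb, sb) in itertools.combinations(models, 2):
        rows.append(
            {
                "model_a": f"{names[ea]}/seed{sa}",
                "model_b": f"{names[eb]}/seed{sb}",
                "cka": cka(grams[(ea, sa)], grams[(eb, sb)]),
                "mcc_inter": mcc_inter(preds[(ea, sa)], preds[(eb, sb)]),
            }
        )
    if len(rows) < 3:
        raise InsufficientDataError(
            f"need at least 3 model pairs, got {len(rows)}"
        )
    pairs = pd.DataFrame(rows)
    if np.std(pairs["cka"]) == 0.0 or np.std(pairs["mcc_inter"]) == 0.0:
        return CorrelationReport(
            r=float("nan"), p=float("nan"), pairs=pairs,
            kernel_name=kernel, degenerate=True,
        )
    r, p = stats.pearsonr(pairs["cka"], pairs["mcc_inter"])
    return CorrelationReport(
        r=float(r), p=float(p), pairs=pairs, kernel_name=kernel,
    )
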