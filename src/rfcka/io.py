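"""Delimited-text input/output for embeddings, labels, Gram matrices, SMILES.

Matrix files are comma- or tab-separated with a header row; the first column
holds sample ids and the remaining columns numeric features.  Label files are
two columns (sample id, 0/1).  SMILES files carry one record per line, either
a bare SMILES string or ``SMILES<TAB>id``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError, InvalidInputError
from .kernels import EmbeddingMatrix, GramMatrix, LabelVector

__all__ = [
    "read_embedding",
    "write_embedding",
    "read_labels",
    "write_labels",
    "read_gram",
    "write_gram",
    "read_smiles",
    "file_digest",
    "align_labels",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None lets pandas sniff comma vs tab
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_embedding(path: str | Path) -> EmbeddingMatrix:
    df = _read_table(path)
    if df.shape[1] < 1:
        raise EmptyInputError(f"{path}: no feature columns")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InvalidInputError(f"{path}: non-numeric feature values") from exc
    return EmbeddingMatrix(values, tuple(str(i) for i in df.index))


def write_embedding(X: EmbeddingMatrix, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        X.values,
        index=[str(i) for i in X.sample_ids],
        columns=[f"f{j}" for j in range(X.n_features)],
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_labels(path: str | Path) -> tuple[tuple, LabelVector]:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] != 1:
        raise InvalidInputError(f"{path}: label file must have exactly two columns")
    ids = tuple(str(i) for i in df.index)
    return ids, LabelVector(df.iloc[:, 0].to_numpy())


def write_labels(sample_ids, y: LabelVector, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame({"label": y.labels}, index=[str(i) for i in sample_ids])
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_gram(path: str | Path, kernel_name: str = "unknown") -> GramMatrix:
    df = _read_table(path)
    return GramMatrix(
        df.to_numpy(dtype=float), kernel_name, tuple(str(i) for i in df.index)
    )


def write_gram(K: GramMatrix, path: str | Path, sep: str = ",") -> None:
    ids = [str(i) for i in K.sample_ids]
    df = pd.DataFrame(K.values, index=ids, columns=ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_smiles(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, smiles) records; ids default to the 1-based line number."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2:
            records.append((parts[1].strip(), parts[0].strip()))
        else:
            records.append((str(lineno), parts[0]))
    if not records:
        raise EmptyInputError(f"{path}: no SMILES records")
    return records


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for result provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def align_labels(X: EmbeddingMatrix, label_ids: tuple, y: LabelVector) -> LabelVector:
    """Reorder labels to match an embedding's sample ids."""
    lookup = {str(i): int(lab) for i, lab in zip(label_ids, y.labels)}
    missing = [i for i in X.sample_ids if str(i) not in lookup]
    if missing:
        raise AlignmentError(f"labels missing for sample ids {missing[:5]}")
    return LabelVector(np.array([lookup[str(i)] for i in X.sample_ids]))
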