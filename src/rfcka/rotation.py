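"""Rotations of feature space and the rotational-invariance check for learners.

A learning algorithm L is rotationally invariant when, for any training set S,
rotation M in SO(p), and test point x, L[S](x) = L[MS](Mx): rotating the whole
problem leaves the predictions unchanged.  Logistic regression with isotropic
regularization has this property; decision trees (axis-aligned splits) and
hence random forests do not.  :func:`invariance_check` turns the definition
into a finite test with a disagreement tolerance, because finite-precision
optimizers are only approximately invariant.

Reflections (determinant -1) are excluded: every generated matrix lies in
SO(p) proper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    ContractViolationError,
    DimensionMismatchError,
    InvalidInputError,
    InvalidParameterError,
)
from .kernels import EmbeddingMatrix, LabelVector

__all__ = [
    "RotationMatrix",
    "LabelledDataset",
    "LearnerContract",
    "planar_rotation",
    "random_rotation",
    "rotate",
    "invariance_check",
    "logistic_learner",
    "tree_learner",
]


@dataclass(frozen=True)
class RotationMatrix:
    """A p x p element of SO(p): orthogonal with determinant +1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.values, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise InvalidInputError("rotation matrix must be square")
        p = M.shape[0]
        if not np.allclose(M.T @ M, np.eye(p), atol=1e-10):
            raise InvalidInputError("matrix is not orthogonal")
        if not np.isclose(np.linalg.det(M), 1.0, atol=1e-10):
            raise InvalidInputError("determinant must be +1 (no reflections)")
        object.__setattr__(self, "values", M)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def inverse(self) -> "RotationMatrix":
        return RotationMatrix(self.values.T)


@dataclass(frozen=True)
class LabelledDataset:
    """A feature matrix paired with aligned binary labels (a training set)."""

    X: EmbeddingMatrix
    y: LabelVector

    def __post_init__(self) -> None:
        if len(self.y) != self.X.n_samples:
            raise DimensionMismatchError("labels not aligned with features")


@dataclass(frozen=True)
class LearnerContract:
    """A deterministic learner as a (fit, predict) pair.

    ``fit`` maps a :class:`LabelledDataset` to an opaque fitted model;
    ``predict`` maps (model, features) to integer labels.  Determinism under
    the learner's fixed seed is part of the contract and is verified by
    :func:`invariance_check`.
    """

    fit: Callable[[LabelledDataset], Any]
    predict: Callable[[Any, EmbeddingMatrix], np.ndarray]
    name: str = "learner"


def planar_rotation(theta: float) -> RotationMatrix:
    """The 2-D rotation by ``theta`` radians."""
    if not np.isfinite(theta):
        raise InvalidInputError("theta must be finite")
    c, s = np.cos(theta), np.sin(theta)
    return RotationMatrix(np.array([[c, -s], [s, c]]))


def random_rotation(p: int, rng: np.random.Generator | int | None = None) -> RotationMatrix:
    """A Haar-like random element of SO(p).

    QR-decomposes a Gaussian matrix, fixes the signs of R's diagonal (Haar on
    O(p)), then flips one column if needed to land in the det = +1 component.
    """
    if p < 2:
        raise InvalidParameterError("rotation dimension must be >= 2")
    rng = np.random.default_rng(rng)
    A = rng.standard_normal((p, p))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return RotationMatrix(Q)


def rotate(X: EmbeddingMatrix, M: RotationMatrix) -> EmbeddingMatrix:
    """Apply M to every row of X; an isometry of feature space."""
    if X.n_features != M.p:
        raise DimensionMismatchError(
            f"cannot rotate {X.n_features}-D features with a {M.p}x{M.p} rotation"
        )
    return EmbeddingMatrix(X.values @ M.values.T, X.sample_ids)


def invariance_check(
    learner: LearnerContract,
    S: LabelledDataset,
    X_test: EmbeddingMatrix,
    M: RotationMatrix,
    tolerance: float = 0.02,
) -> tuple[bool, float]:
    """Test whether a learner's predictions survive a joint rotation.

    Fits the learner on S and on the rotated copy MS, predicts X_test with the
    first and the rotated X_test with the second, and reports the fraction of
    disagreeing predictions.  Passes iff that fraction is <= ``tolerance``.

    Two identical fits on S are compared first; if they disagree the learner
    violates its determinism contract and the check is meaningless.
    """
    model_a = learner.fit(S)
    model_b = learner.fit(S)
    pred_a = np.asarray(learner.predict(model_a, X_test))
    pred_b = np.asarray(learner.predict(model_b, X_test))
    if not np.array_equal(pred_a, pred_b):
        raise ContractViolationError(
            f"learner {learner.name!r} is not deterministic: two identical "
            "fits produced different predictions"
        )
    S_rot = LabelledDataset(rotate(S.X, M), S.y)
    model_rot = learner.fit(S_rot)
    pred_rot = np.asarray(learner.predict(model_rot, rotate(X_test, M)))
    disagreement = float(np.mean(pred_a != pred_rot))
    return disagreement <= tolerance, disagreement


# ---------------------------------------------------------------------------
# fixture learners exercising the two sides of the dichotomy
# ---------------------------------------------------------------------------


def logistic_learner(C: float = 1.0) -> LearnerContract:
    """L2-regularized logistic regression — rotationally invariant.

    The penalty is isotropic and lbfgs is run to tight tolerance so that the
    fitted decision boundary co-rotates with the data to high accuracy.
    """

    def fit(S: LabelledDataset):
        model = LogisticRegression(
            C=C, solver="lbfgs", tol=1e-12, max_iter=10_000
        )
        model.fit(S.X.values, S.y.labels)
        return model

    def predict(model, X: EmbeddingMatrix) -> np.ndarray:
        return model.predict(X.values)

    return LearnerContract(fit=fit, predict=predict, name="logistic")


def tree_learner(seed: int = 0, max_depth: int | None = None) -> LearnerContract:
    """A single decision tree — axis-aligned splits, not rotationally invariant."""

    def fit(S: LabelledDataset):
        model = DecisionTreeClassifier(random_state=seed, max_depth=max_depth)
        model.fit(S.X.values, S.y.labels)
        return model

    def predict(model, X: EmbeddingMatrix) -> np.ndarray:
        return model.predict(X.values)

    return LearnerContract(fit=fit, predict=predict, name="tree")
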