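"""L1-regularized L2-loss linear support vector machine.

The classifier minimizes, over weight vectors w in R^n and with no intercept,

    ||w||_1  +  C * sum_i max(0, 1 - y_i <w, x_i>)^2

for instance-label pairs (x_i, y_i), y_i in {-1, +1}, i = 1..l, where C > 0
trades sparsity against the squared hinge loss.  The L1 penalty drives most
weights to exactly zero, so the surviving nonzero components mark the protein
families that the model actually uses to separate degraders from
non-degraders.  Training delegates to LIBLINEAR's coordinate-descent solver
for this exact formulation (via scikit-learn); :func:`objective` exposes the
objective itself so solutions can be verified independently.

The decision rule is sign(<w, x>), with a tie at exactly 0 resolved to the
negative class — the conservative choice for a degrader call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

#: weights with |w_j| below this are reported as zero (absorbs solver numerics)
NONZERO_TOL = 1e-9


@dataclass
class SparseLinearModel:
    """Weight vector and penalty of one trained sparse linear SVM."""

    w: np.ndarray
    C: float
    family_ids: list
    encoding: str = "binary"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.w.shape != (len(self.family_ids),):
            raise ValueError("weight vector length must match family_ids")

    @property
    def nonzero_mask(self) -> np.ndarray:
        return np.abs(self.w) > NONZERO_TOL

    @property
    def n_nonzero(self) -> int:
        return int(self.nonzero_mask.sum())

    @property
    def positive_mask(self) -> np.ndarray:
        """Families with strictly positive weight (degrader-associated)."""
        return self.w > NONZERO_TOL


def objective(w, X, y, C: float) -> float:
    """Evaluate ||w||_1 + C * sum_i max(0, 1 - y_i <w, x_i>)^2 (no intercept)."""
    w = np.asarray(w, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape != (y.size, w.size):
        raise ValueError(
            f"dimension mismatch: X is {X.shape}, expected ({y.size}, {w.size})"
        )
    if C < 0:
        raise ValueError("C must be non-negative")
    margins = 1.0 - y * (X @ w)
    hinge = np.clip(margins, 0.0, None)
    return float(np.abs(w).sum() + C * (hinge ** 2).sum())


def train(
    X,
    y,
    C: float,
    tolerance: float = 1e-6,
    *,
    family_ids: Optional[Sequence[str]] = None,
    encoding: str = "binary",
    max_iter: int = 100_000,
) -> SparseLinearModel:
    """Fit the sparse linear SVM at penalty *C*.

    Deterministic for fixed inputs and tolerance.  Requires both classes to
    be present and all features finite; C must be strictly positive (C = 0
    would make the problem degenerate, with w = 0 as the trivial solution).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of samples")
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("labels must be +1 or -1")
    if np.unique(y).size < 2:
        raise ValueError("training requires at least one sample of each class")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if C <= 0:
        raise ValueError("C must be strictly positive")
    clf = LinearSVC(
        penalty="l1",
        loss="squared_hinge",
        dual=False,
        C=C,
        fit_intercept=False,
        tol=tolerance,
        max_iter=max_iter,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    if family_ids is None:
        family_ids = [f"f{j}" for j in range(X.shape[1])]
    return SparseLinearModel(w=w, C=float(C), family_ids=list(family_ids), encoding=encoding)


def decision_function(model: SparseLinearModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.w.size:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} features vs model with {model.w.size}"
        )
    return X @ model.w


def predict(model: SparseLinearModel, x) -> Tuple[int, float]:
    """Classify one sample: label +1 iff <w, x> > 0, else -1 (ties negative)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.w.size:
        raise ValueError(
            f"dimension mismatch: sample has {x.size} features, model {model.w.size}"
        )
    value = float(np.dot(model.w, x))
    return (1 if value > 0 else -1), value


def predict_many(model: SparseLinearModel, X) -> Tuple[np.ndarray, np.ndarray]:
    values = decision_function(model, X)
    labels = np.where(values > 0, 1, -1)
    return labels, values
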