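"""Spectral regression discriminant analysis (SRDA) and 2-D normalisation.

SRDA finds the ``c - 1`` discriminant directions of linear discriminant
analysis by *regression*: the class-indicator vectors are orthogonalised
against the constant vector (Gram-Schmidt, realised here with a QR
decomposition) to give ``c - 1`` response vectors, and each response is
fitted by ridge-regularised least squares on the centred feature matrix.
This avoids the dense eigendecomposition of classical LDA and scales to
high-dimensional feature spaces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class ProjectionModel:
    """A fitted SRDA projection: ``z = (x - mean) @ weights``."""

    weights: np.ndarray  # (input_dim, c - 1)
    mean: np.ndarray  # (input_dim,)
    classes: np.ndarray  # sorted class labels seen in training
    reg: float

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "mean": self.mean.tolist(),
            "classes": np.asarray(self.classes).tolist(),
            "reg": self.reg,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            mean=np.asarray(d["mean"], dtype=float),
            classes=np.asarray(d["classes"]),
            reg=float(d["reg"]),
        )


def fit_srda(X: np.ndarray, y: np.ndarray, reg: float = 0.01) -> ProjectionModel:
    """Fit the c-1 dimensional SRDA projection on training data only.

    Parameters
    ----------
    X : (n_samples, n_features) feature matrix.
    y : (n_samples,) class labels (at least two classes).
    reg : ridge regularisation strength; tolerates zero-variance columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    classes = np.unique(y)
    c = classes.size
    if c < 2:
        raise ValueError("need at least two classes")
    n, d = X.shape
    if n < c:
        raise ValueError(f"need at least {c} samples for {c} classes")

    mean = X.mean(axis=0)
    Xc = X - mean

    # Orthogonalise [1, indicator_1, ..., indicator_c]; the constant column is
    # discarded and the last indicator is linearly dependent, leaving c - 1
    # orthonormal responses.
    E = np.zeros((n, c + 1))
    E[:, 0] = 1.0
    for k, cls in enumerate(classes):
        E[y == cls, k + 1] = 1.0
    Q, _ = np.linalg.qr(E)
    Y = Q[:, 1:c]

    G = Xc.T @ Xc + reg * np.eye(d)
    W = np.linalg.solve(G, Xc.T @ Y)
    return ProjectionModel(weights=W, mean=mean, classes=classes, reg=float(reg))


def transform(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Project features into the discriminant space (deterministic linear map)."""
    X = np.asarray(X, dtype=float)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[None, :]
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model input "
            f"dimension {model.weights.shape[0]}"
        )
    Z = (X - model.mean) @ model.weights
    return Z[0] if one_dim else Z


def normalize_first_two(reduced: np.ndarray) -> np.ndarray:
    """Min-max normalise the first two reduced dimensions to [0, 1].

    Normalisation is over the supplied point set; a constant column (or a
    single point) maps to 0.5 with a warning.
    """
    Z = np.asarray(reduced, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("need a matrix with at least two columns")
    out = np.empty((Z.shape[0], 2))
    for j in (0, 1):
        col = Z[:, j]
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            warnings.warn(f"constant reduced dimension {j + 1}; mapping to 0.5", stacklevel=2)
            out[:, j] = 0.5
        else:
            out[:, j] = (col - lo) / (hi - lo)
    return out
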