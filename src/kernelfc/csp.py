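"""CSP-style generalized eigendecomposition on covariance or FC matrices.

Classic common spatial patterns solve the generalized eigenproblem
``S1 w = lambda (S1 + S2) w`` for the class-mean matrices S1, S2 and keep
the most discriminative eigenvectors.  Here the class-mean matrix may be
any symmetric functional-connectivity matrix, not only a covariance; a
small ridge keeps the composite matrix positive definite (PLV matrices
need not be).

The per-trial feature is the "pattern vector": the upper triangle of the
projected matrix ``W^T M W``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["CSPModel", "fit_csp", "project_features", "CSPProjector"]


@dataclass
class CSPModel:
    """Generalized eigenvectors of (S1, S1 + S2) with their eigenvalues."""

    filters: np.ndarray  # (C, K)
    eigenvalues: np.ndarray  # (K,), sorted descending, in [0, 1]
    class_means: tuple[np.ndarray, np.ndarray]
    ridge: float

    @property
    def n_components(self) -> int:
        return self.filters.shape[1]


def _check_symmetric(mats: np.ndarray) -> np.ndarray:
    mats = np.asarray(mats, dtype=np.float64)
    if not np.allclose(mats, np.swapaxes(mats, -1, -2), atol=1e-8):
        raise ValueError("input matrices must be symmetric")
    return mats


def fit_csp(
    matrices: np.ndarray,
    labels: np.ndarray,
    n_components: int = 3,
    ridge: float | None = None,
) -> CSPModel:
    """Fit on per-trial symmetric matrices (R, C, C) with binary labels.

    ``ridge=None`` uses the default ``1e-6 * trace(S)/C`` regularization;
    pass 0 to disable.  Keeps the ``n_components`` eigenvectors with the
    largest eigenvalues (eigenvalues lie in [0, 1]; label swap maps them
    to their complements 1 - lambda).
    """
    matrices = _check_symmetric(matrices)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes; got {classes}")
    s1 = matrices[labels == classes[1]].mean(axis=0)
    s2 = matrices[labels == classes[0]].mean(axis=0)
    c = s1.shape[0]
    if ridge is None:
        ridge = 1e-6 * np.trace(s1 + s2) / (2 * c)
    s1 = s1 + ridge * np.eye(c)
    s2 = s2 + ridge * np.eye(c)
    composite = s1 + s2
    try:
        eigvals, eigvecs = linalg.eigh(s1, composite)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "composite matrix is singular even after ridge regularization"
        ) from exc
    order = np.argsort(eigvals)[::-1]
    k = min(n_components, c)
    eigvals = np.clip(eigvals[order][:k], 0.0, 1.0)
    filters = eigvecs[:, order][:, :k]
    # deterministic sign: largest-magnitude entry of each filter is positive
    flip = np.sign(filters[np.abs(filters).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    filters = filters * flip
    return CSPModel(
        filters=filters,
        eigenvalues=eigvals,
        class_means=(s1, s2),
        ridge=float(ridge),
    )


def project_features(matrix: np.ndarray, model: CSPModel) -> np.ndarray:
    """Upper triangle (incl. diagonal) of W^T M W: K(K+1)/2 features."""
    matrix = np.asarray(matrix, dtype=np.float64)
    c = model.filters.shape[0]
    if matrix.shape != (c, c):
        raise ValueError(f"matrix shape {matrix.shape} mismatches C={c}")
    projected = model.filters.T @ matrix @ model.filters
    iu, ju = np.triu_indices(model.n_components)
    return projected[iu, ju]


class CSPProjector(TransformerMixin, BaseEstimator):
    """sklearn transformer: per-trial matrices (R, C, C) -> (R, K(K+1)/2)."""

    def __init__(self, n_components: int = 3, ridge: float | None = None):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("CSP is supervised: labels are required")
        self.model_ = fit_csp(
            X, y, n_components=self.n_components, ridge=self.ridge
        )
        self.eigenvalues_ = self.model_.eigenvalues
        self.filters_ = self.model_.filters
        return self

    def transform(self, X) -> np.ndarray:
        X = _check_symmetric(X)
        w = self.model_.filters
        projected = np.einsum("ck,rcd,dm->rkm", w, X, w)
        iu, ju = np.triu_indices(self.model_.n_components)
        return projected[:, iu, ju]
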