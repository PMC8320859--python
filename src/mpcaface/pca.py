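"""Single-level PCA of shape or texture vectors.

The model is the classical point-distribution / appearance eigenmodel: the
sample covariance ``C = (1/(N-1)) * sum_i (z_i - zbar)(z_i - zbar)^T`` is
eigendecomposed, eigenvalues are ranked in descending order, and any vector
``z`` is approximated as ``zbar + sum_l a_l u_l`` with coefficients obtained
by scalar products against the orthonormal eigenvectors,
``a_l = u_l . (z - zbar)``.  Dividing a coefficient by ``sqrt(lambda_l)``
gives a *standardized score* with unit in-sample variance, which makes
components comparable across models (and, later, across hierarchy levels).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: eigenvalues below this fraction of the largest are treated as null space
RANK_RTOL = 1e-10


def covariance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Sample covariance about the mean with divisor ``N - 1``."""
    X = np.atleast_2d(np.asarray(vectors, float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 vectors for a covariance matrix")
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / (X.shape[0] - 1)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude element is positive."""
    vectors = vectors.copy()
    for j in range(vectors.shape[1]):
        i = int(np.argmax(np.abs(vectors[:, j])))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return vectors


def eigen_decompose(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending, sign-fixed eigendecomposition of a symmetric PSD matrix.

    Tiny negative eigenvalues from round-off are clipped to zero.  Ordering is
    stable under ties: sorted by (-eigenvalue, original index).
    """
    vals, vecs = np.linalg.eigh(C)
    order = np.lexsort((np.arange(vals.size), -vals))
    vals, vecs = vals[order], vecs[:, order]
    if vals.size and vals[0] > 0:
        floor = -1e-8 * vals[0]
        if np.any(vals < floor):
            logger.warning("clipping eigenvalues below %g to zero", floor)
    vals = np.clip(vals, 0.0, None)
    ties = np.flatnonzero(np.isclose(np.diff(vals), 0, atol=0) & (vals[:-1] > 0))
    if ties.size:
        logger.info("degenerate eigenvalues at positions %s", ties.tolist())
    return vals, _fix_signs(vecs)


def _resolve_retention(vals: np.ndarray, retain) -> int:
    """Number of components to keep under a count / fraction / default rule."""
    rank = int(np.sum(vals > RANK_RTOL * vals[0])) if vals.size and vals[0] > 0 else 0
    if retain is None:
        return rank
    if isinstance(retain, float) and 0 < retain < 1:
        total = vals.sum()
        cum = np.cumsum(vals) / total if total > 0 else np.ones_like(vals)
        return max(1, int(np.searchsorted(cum, retain) + 1))
    retain = int(retain)
    if retain > rank:
        logger.warning("retain=%d exceeds numerical rank %d; truncating", retain, rank)
        return rank
    if retain < 1:
        raise ValueError("retain must be positive")
    return retain


class ShapePCA(BaseEstimator, TransformerMixin):
    """Eigenmodel of shape (or texture) vectors.

    Parameters
    ----------
    n_components : int, float in (0, 1), or None
        Components to retain: an explicit count, a variance fraction, or
        ``None`` to keep everything above numerical rank tolerance.

    Attributes
    ----------
    mean_ : ndarray (p,)
        Sample mean vector ``zbar``.
    eigenvalues_ : ndarray (n_components_,)
        Retained eigenvalues, descending, non-negative.
    components_ : ndarray (n_components_, p)
        Retained orthonormal eigenvectors, one per row.
    n_components_ : int
        Retained count.
    """

    def __init__(self, n_components: int | float | None = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "ShapePCA":
        X = np.atleast_2d(np.asarray(X, float))
        C = covariance_matrix(X)
        vals, vecs = eigen_decompose(C)
        r = _resolve_retention(vals, self.n_components)
        self.mean_ = X.mean(axis=0)
        self.eigenvalues_ = vals[:r]
        self.components_ = vecs[:, :r].T
        self.n_components_ = r
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "mean_"):
            raise ValueError("ShapePCA instance is not fitted yet")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project vectors onto the retained eigenvectors (Eq.-4 scalar products)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.mean_.size:
            raise ValueError(
                f"vector length {X.shape[1]} != model length {self.mean_.size}"
            )
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, coeffs: np.ndarray) -> np.ndarray:
        """Rebuild vectors as ``mean + sum_l a_l u_l``."""
        self._check_fitted()
        coeffs = np.atleast_2d(np.asarray(coeffs, float))
        if coeffs.shape[1] > self.n_components_:
            raise ValueError("more coefficients than retained components")
        return self.mean_ + coeffs @ self.components_[: coeffs.shape[1]]

    def standardize_scores(self, coeffs: np.ndarray) -> np.ndarray:
        """Divide coefficients by sqrt(eigenvalue); near-null components dropped."""
        self._check_fitted()
        coeffs = np.atleast_2d(np.asarray(coeffs, float))
        tol = RANK_RTOL * self.eigenvalues_[0] if self.n_components_ else 0.0
        keep = self.eigenvalues_[: coeffs.shape[1]] > tol
        if not keep.all():
            warnings.warn(
                "dropping %d component(s) with near-zero eigenvalue from "
                "standardized scores" % int((~keep).sum())
            )
        return coeffs[:, keep] / np.sqrt(self.eigenvalues_[: coeffs.shape[1]][keep])

    def mode_of_variation(self, l: int, c: float) -> np.ndarray:
        """``mean + c * sqrt(lambda_l) * u_l`` (c = -1, 0, +1 gives mean -/+ SD)."""
        self._check_fitted()
        if not 0 <= l < self.n_components_:
            raise ValueError(f"component index {l} out of range")
        return self.mean_ + c * np.sqrt(self.eigenvalues_[l]) * self.components_[l]

    def save(self, directory: str | Path) -> None:
        """Serialize to flat CSV files (eigenvalues.csv, basis.csv)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"component": np.arange(1, self.n_components_ + 1),
             "eigenvalue": self.eigenvalues_}
        ).to_csv(directory / "eigenvalues.csv", index=False)
        # basis.csv: first row the mean, then one row per eigenvector
        basis = np.vstack([self.mean_, self.components_]) if self.n_components_ else self.mean_[None]
        pd.DataFrame(basis).to_csv(directory / "basis.csv", index=False, header=False)

    @classmethod
    def load(cls, directory: str | Path) -> "ShapePCA":
        directory = Path(directory)
        vals = pd.read_csv(directory / "eigenvalues.csv")["eigenvalue"].to_numpy()
        basis = pd.read_csv(directory / "basis.csv", header=None).to_numpy(float)
        model = cls(n_components=len(vals))
        model.mean_ = basis[0]
        model.components_ = basis[1:]
        model.eigenvalues_ = vals
        model.n_components_ = len(vals)
        model.n_features_in_ = basis.shape[1]
        return model


# ---------------------------------------------------------------------------
# functional wrappers

def fit_pca(vectors: np.ndarray, retain: int | float | None = None) -> ShapePCA:
    return ShapePCA(n_components=retain).fit(vectors)

def project(model: ShapePCA, z: np.ndarray) -> np.ndarray:
    return model.transform(np.atleast_2d(z))[0]

def reconstruct(model: ShapePCA, coeffs: np.ndarray) -> np.ndarray:
    return model.inverse_transform(np.atleast_2d(coeffs))[0]

def standardize_scores(model: ShapePCA, coeffs: np.ndarray) -> np.ndarray:
    return model.standardize_scores(np.atleast_2d(coeffs))[0]

def mode_of_variation(model: ShapePCA, l: int, c: float) -> np.ndarray:
    return model.mode_of_variation(l, c)
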