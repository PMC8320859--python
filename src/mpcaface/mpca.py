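"""Multilevel principal components analysis (mPCA).

A three-level hierarchy (e.g. biological sex / subject / facial expression
for static faces, or subject / smile phase / frame for dynamic mouth data)
is used to build one covariance matrix per level:

* **bottom** — covariance of the observations in each bottom cell about that
  cell's mean, averaged over cells;
* **middle** — covariance of the middle-unit means about their parent-unit
  mean, computed within each top unit and averaged across top units;
* **top** — covariance of the top-unit means about the mean of those means
  (sample covariance with divisor ``G - 1``; its rank is at most ``G - 1``,
  so two groups give exactly one non-zero eigenvalue).

PCA is run on each level's matrix separately; eigenvectors are orthonormal
*within* a level but need not be orthogonal *between* levels.  A new vector
``z`` is therefore fitted jointly: the per-level coefficients minimize

    Delta = || z - zbar - U1 a1 - U2 a2 - U3 a3 ||^2

either by direct linear least squares on the column-stacked basis or by
plain gradient iteration ``a <- a - kappa * dDelta/da`` with ``kappa = 0.01``
from an all-zero start; the two routes agree (both converge to the
minimum-norm least-squares solution).  Standardized per-level scores divide
each coefficient by the square root of its eigenvalue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ShapeDataset
from .pca import RANK_RTOL, _resolve_retention, eigen_decompose

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HierarchySpec:
    """Binding of label columns to the three levels of the model.

    ``columns`` gives, top to bottom, the label column that defines each
    level's units.  ``bottom_averaging`` controls how per-cell bottom
    covariances are pooled: ``"flat"`` averages over all middle units
    directly (the static-faces convention, e.g. over all 80 subjects);
    ``"nested"`` first averages within each top unit, then across top units
    (the smile convention: over phases per subject, then over subjects).
    """

    level_names: tuple[str, str, str]
    columns: tuple[str, str, str]
    bottom_averaging: str = "flat"

    def __post_init__(self):
        if len(self.level_names) != 3 or len(self.columns) != 3:
            raise ValueError("exactly three levels are supported")
        if self.bottom_averaging not in ("flat", "nested"):
            raise ValueError("bottom_averaging must be 'flat' or 'nested'")

    @classmethod
    def static_faces(cls) -> "HierarchySpec":
        """Sex / subject / expression hierarchy for static face datasets."""
        return cls(("group", "subject", "condition"),
                   ("group_id", "subject_id", "condition_id"), "flat")

    @classmethod
    def smile_frames(cls) -> "HierarchySpec":
        """Subject / smile-phase / within-phase hierarchy for trajectories."""
        return cls(("subject", "phase", "within_phase"),
                   ("subject_id", "condition_id", "frame_index"), "nested")


def _cov_about(X: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Covariance of rows of X about a given center, divisor N - 1."""
    Xc = X - center
    return (Xc.T @ Xc) / (X.shape[0] - 1)


def level_covariances(
    dataset_or_X,
    hierarchy: HierarchySpec,
    labels: pd.DataFrame | None = None,
    weighted: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the (top, middle, bottom) covariance matrices for a hierarchy.

    Accepts a :class:`ShapeDataset` or an ``(n, p)`` matrix plus a label
    frame.  ``weighted=True`` weights covariance averages by the number of
    observations in each unit instead of averaging unweighted.
    """
    if isinstance(dataset_or_X, ShapeDataset):
        X, labels = dataset_or_X.X, dataset_or_X.labels
    else:
        X = np.atleast_2d(np.asarray(dataset_or_X, float))
        if labels is None:
            raise ValueError("labels required when passing a raw matrix")
    top_col, mid_col, _ = hierarchy.columns
    p = X.shape[1]
    lab = labels.reset_index(drop=True)

    top_ids = lab[top_col].unique()
    if len(top_ids) < 2:
        raise ValueError("top level needs at least two units")

    # --- bottom level: per (top, mid) cell, obs about the cell mean --------
    mid_means: dict[tuple, np.ndarray] = {}
    bottom_by_top: dict[object, list[tuple[np.ndarray, int]]] = {t: [] for t in top_ids}
    for (t, m), idx in lab.groupby([top_col, mid_col], sort=False).groups.items():
        rows = X[np.asarray(idx)]
        mid_means[(t, m)] = rows.mean(axis=0)
        if rows.shape[0] < 2:
            logger.info("unit (%s, %s) has a single observation; zero bottom "
                        "covariance contribution", t, m)
            cov = np.zeros((p, p))
        else:
            cov = _cov_about(rows, mid_means[(t, m)])
        bottom_by_top[t].append((cov, rows.shape[0]))

    def _avg(mats_weights):
        mats = [m for m, _ in mats_weights]
        if weighted:
            w = np.array([n for _, n in mats_weights], float)
            w = w / w.sum()
            return np.tensordot(w, np.stack(mats), axes=1)
        return np.mean(np.stack(mats), axis=0)

    if hierarchy.bottom_averaging == "flat":
        bottom = _avg([mw for t in top_ids for mw in bottom_by_top[t]])
    else:
        bottom = _avg([(_avg(bottom_by_top[t]), len(bottom_by_top[t]))
                       for t in top_ids])

    # --- middle level: mid-unit means about their top-unit mean ------------
    mid_covs = []
    top_means = {}
    for t in top_ids:
        means = np.stack([mid_means[(tt, m)] for (tt, m) in mid_means if tt == t])
        top_means[t] = means.mean(axis=0)
        if means.shape[0] < 2:
            logger.info("top unit %s has a single middle unit; zero middle "
                        "covariance contribution", t)
            mid_covs.append((np.zeros((p, p)), means.shape[0]))
        else:
            mid_covs.append((_cov_about(means, top_means[t]), means.shape[0]))
    middle = _avg(mid_covs)

    # --- top level: top-unit means about their own mean ---------------------
    tm = np.stack([top_means[t] for t in top_ids])
    top = _cov_about(tm, tm.mean(axis=0))
    return top, middle, bottom


class MultilevelPCA:
    """Three-level mPCA model with a joint coefficient fit.

    Parameters
    ----------
    hierarchy : HierarchySpec
        Level-to-label-column binding (see :class:`HierarchySpec`).
    n_components : tuple of 3 (int or None), optional
        Per-level retention ``(l1, l2, l3)``; ``None`` keeps everything above
        the numerical-rank tolerance at that level.
    weighted : bool
        Weight covariance averages by unit sizes instead of unweighted means.
    kappa : float
        Gradient-iteration step size.
    grad_tol : float
        Largest coefficient update below which the iteration stops.
    grad_max_iter : int
        Gradient-iteration cap.

    Attributes
    ----------
    grand_mean_ : ndarray (p,) — mean of all training vectors.
    level_covariances_ : list of three (p, p) matrices, top to bottom.
    eigenvalues_ : list of three descending eigenvalue arrays.
    components_ : list of three (r_level, p) orthonormal eigenvector stacks.
    n_components_ : tuple of retained counts per level.
    level_names_ : names from the hierarchy spec.
    """

    def __init__(
        self,
        hierarchy: HierarchySpec | None = None,
        n_components: tuple[int | None, int | None, int | None] = (None, None, None),
        weighted: bool = False,
        kappa: float = 0.01,
        grad_tol: float = 1e-12,
        grad_max_iter: int = 100_000,
    ):
        self.hierarchy = hierarchy
        self.n_components = n_components
        self.weighted = weighted
        self.kappa = kappa
        self.grad_tol = grad_tol
        self.grad_max_iter = grad_max_iter

    # -- estimator plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("hierarchy", "n_components", "weighted", "kappa",
                 "grad_tol", "grad_max_iter")}

    def set_params(self, **params) -> "MultilevelPCA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "grand_mean_"):
            raise ValueError("MultilevelPCA instance is not fitted yet")

    # -- fitting ------------------------------------------------------------
    def fit(self, X, labels: pd.DataFrame | None = None) -> "MultilevelPCA":
        hierarchy = self.hierarchy or HierarchySpec.static_faces()
        if isinstance(X, ShapeDataset):
            X, labels = X.X, X.labels
        X = np.atleast_2d(np.asarray(X, float))
        covs = level_covariances(X, hierarchy, labels, weighted=self.weighted)
        self.hierarchy_ = hierarchy
        self.level_names_ = hierarchy.level_names
        self.grand_mean_ = X.mean(axis=0)
        self.level_covariances_ = list(covs)
        self.eigenvalues_, self.components_ = [], []
        retained = []
        for C, retain in zip(covs, self.n_components):
            vals, vecs = eigen_decompose(C)
            r = _resolve_retention(vals, retain)
            r = max(r, 1) if vals.size else 0  # keep at least one component
            self.eigenvalues_.append(vals[:r])
            self.components_.append(vecs[:, :r].T)
            retained.append(r)
        self.n_components_ = tuple(retained)
        self.n_features_in_ = X.shape[1]
        return self

    # -- joint coefficient fit ----------------------------------------------
    @property
    def _stacked_basis(self) -> np.ndarray:
        return np.vstack(self.components_).T  # (p, l1+l2+l3)

    def _split(self, a: np.ndarray) -> list[np.ndarray]:
        out, i = [], 0
        for r in self.n_components_:
            out.append(a[..., i:i + r])
            i += r
        return out

    def project(self, z: np.ndarray, method: str = "direct") -> list[np.ndarray]:
        """Per-level coefficients minimizing the joint residual cost.

        ``method="direct"`` solves the least-squares problem on the
        column-stacked per-level bases (minimum-norm solution if the stacked
        basis is rank deficient).  ``method="gradient"`` iterates
        ``a <- a - kappa * dDelta/da`` from an all-zero start until the
        largest coefficient update falls below ``grad_tol``.
        """
        self._check_fitted()
        z = np.asarray(z, float)
        if z.shape[-1] != self.grand_mean_.size:
            raise ValueError(
                f"vector length {z.shape[-1]} != model length {self.grand_mean_.size}"
            )
        single = z.ndim == 1
        Z = np.atleast_2d(z) - self.grand_mean_
        U = self._stacked_basis
        if method == "direct":
            A, _, rank, _ = np.linalg.lstsq(U, Z.T, rcond=None)
            if rank < U.shape[1]:
                logger.info("stacked basis rank %d < %d columns; minimum-norm "
                            "solution returned", rank, U.shape[1])
            A = A.T
        elif method == "gradient":
            A = np.stack([self._gradient_fit(U, r) for r in Z])
        else:
            raise ValueError(f"unknown method {method!r}")
        levels = self._split(A)
        return [lv[0] for lv in levels] if single else levels

    def _gradient_fit(self, U: np.ndarray, r: np.ndarray) -> np.ndarray:
        a = np.zeros(U.shape[1])
        G = U.T @ U
        b = U.T @ r
        for it in range(self.grad_max_iter):
            grad = 2.0 * (G @ a - b)          # dDelta/da
            step = self.kappa * grad
            a = a - step
            # the update size bounds the remaining coefficient error, which
            # a cost-decrease criterion does not once Delta plateaus
            if np.max(np.abs(step)) < self.grad_tol:
                return a
        warnings.warn("gradient coefficient fit did not converge within "
                      f"{self.grad_max_iter} iterations; returning best iterate")
        return a

    def reconstruct(self, coeffs: list[np.ndarray]) -> np.ndarray:
        """``grand_mean + sum_levels U_level a_level``."""
        self._check_fitted()
        if len(coeffs) != 3:
            raise ValueError("need one coefficient array per level")
        z = self.grand_mean_.copy()
        for a, comps, r in zip(coeffs, self.components_, self.n_components_):
            a = np.asarray(a, float)
            if a.shape[-1] != r:
                raise ValueError(
                    f"coefficient length {a.shape[-1]} != retained count {r}"
                )
            z = z + a @ comps
        return z

    def standardize(self, coeffs: list[np.ndarray]) -> list[np.ndarray]:
        """Per-level standardized scores: coefficient / sqrt(eigenvalue)."""
        self._check_fitted()
        out = []
        for a, vals in zip(coeffs, self.eigenvalues_):
            a = np.asarray(a, float)
            tol = RANK_RTOL * vals[0] if vals.size and vals[0] > 0 else 0.0
            keep = vals[: a.shape[-1]] > tol
            if not keep.all():
                warnings.warn(
                    "dropping %d near-null component(s) from standardized "
                    "level scores" % int((~keep).sum()))
            out.append(a[..., keep] / np.sqrt(vals[: a.shape[-1]][keep]))
        return out

    def transform(self, X, labels=None, method: str = "direct") -> list[np.ndarray]:
        """Standardized per-level scores for a matrix of vectors."""
        if isinstance(X, ShapeDataset):
            X = X.X
        coeffs = self.project(np.atleast_2d(np.asarray(X, float)), method=method)
        return self.standardize(coeffs)

    def fit_transform(self, X, labels=None) -> list[np.ndarray]:
        return self.fit(X, labels).transform(X)


# ---------------------------------------------------------------------------
# functional wrappers and reporting helpers

def fit_mpca(dataset, hierarchy: HierarchySpec | None = None,
             retain=(None, None, None), weighted: bool = False) -> MultilevelPCA:
    return MultilevelPCA(hierarchy=hierarchy, n_components=tuple(retain),
                         weighted=weighted).fit(dataset)

def mpca_project(model: MultilevelPCA, z, method: str = "direct"):
    return model.project(z, method=method)

def mpca_reconstruct(model: MultilevelPCA, coeffs):
    return model.reconstruct(coeffs)

def standardize_level_scores(model: MultilevelPCA, coeffs):
    return model.standardize(coeffs)


def score_centroids(scores: np.ndarray, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-group means of (standardized) component scores.

    Returns a DataFrame indexed by group with one column per component.
    Groups appear in order of first occurrence; empty groups cannot occur by
    construction of the groupby.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = pd.Series(np.asarray(labels), name="group")
    if len(labels) != scores.shape[0]:
        raise ValueError("one label per score row required")
    df = pd.DataFrame(scores, columns=[f"comp{i + 1}" for i in range(scores.shape[1])])
    df["group"] = labels.values
    return df.groupby("group", sort=False).mean()
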