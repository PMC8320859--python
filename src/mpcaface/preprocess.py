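"""Shape preprocessing: centering, rotational alignment, and scale.

The conventions follow standard geometric morphometrics practice for point
distribution models: shapes are translated so their centroid sits at the
origin, scaled so the *average point-to-centroid distance* equals 1, and
rotated by the closed-form proper orthogonal Procrustes solution.  Full
preprocessing runs a generalized Procrustes (GPA) loop against the evolving
mean shape.  For dynamic mouth data only centering is applied, preserving
scale and orientation changes that are part of the motion itself.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import LandmarkShape, ShapeDataset


def center_shape(shape: LandmarkShape) -> LandmarkShape:
    """Translate so the centroid of the points is the origin."""
    return LandmarkShape(shape.points - shape.centroid(), shape.landmark_names)


def mean_centroid_distance(points: np.ndarray) -> float:
    """Average Euclidean distance of the points from their centroid."""
    c = points.mean(axis=0)
    return float(np.linalg.norm(points - c, axis=1).mean())


def scale_to_unit_centroid_distance(shape: LandmarkShape) -> LandmarkShape:
    """Rescale so the mean point-to-centroid distance equals 1.

    Raises for a degenerate shape whose points all coincide with the centroid.
    """
    s = mean_centroid_distance(shape.points)
    if s <= 1e-300:
        raise ValueError("degenerate shape: all points coincide with the centroid")
    return LandmarkShape(shape.points / s, shape.landmark_names)


def optimal_rotation(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||points @ R - reference||_F.

    Kabsch solution via SVD with the reflection branch excluded.
    """
    H = points.T @ reference
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.eye(H.shape[0])
    D[-1, -1] = sign if sign != 0 else 1.0
    return U @ D @ Vt


def align_rotation(shape: LandmarkShape, reference: LandmarkShape) -> LandmarkShape:
    """Rotate ``shape`` onto ``reference`` (both centered) without reflection."""
    if shape.k != reference.k or shape.d != reference.d:
        raise ValueError(
            f"shape ({shape.k}x{shape.d}) and reference ({reference.k}x{reference.d}) "
            "must have the same landmark count and dimension"
        )
    R = optimal_rotation(shape.points, reference.points)
    return LandmarkShape(shape.points @ R, shape.landmark_names)


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalized Procrustes alignment of a set of shapes.

    Parameters
    ----------
    mode : {"full", "center_only"}
        ``"full"`` iterates centering, unit point-to-centroid scaling, and
        rotation to the running mean until the mean shape stabilizes;
        ``"center_only"`` just removes translation (the convention used for
        dynamic mouth trajectories, where scale change is signal).
    tol : float
        RMS movement of the mean shape below which the loop stops.
    max_iter : int
        Iteration cap for the alignment loop.

    Attributes
    ----------
    mean_shape_ : ndarray of shape (k, d)
        Consensus shape after fitting (``mode="full"`` only).
    n_iter_ : int
        Iterations used.
    """

    def __init__(self, mode: str = "full", tol: float = 1e-9, max_iter: int = 100):
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter

    def _validate(self, X: np.ndarray, d: int) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("need a non-empty (n, k*d) matrix of shape vectors")
        if X.shape[1] % d:
            raise ValueError("vector length not divisible by dimension")
        return X

    def fit(self, X: np.ndarray, y=None, *, d: int = 2) -> "GeneralizedProcrustes":
        self.fit_transform(X, d=d)
        return self

    def fit_transform(self, X: np.ndarray, y=None, *, d: int = 2) -> np.ndarray:
        if self.mode not in ("full", "center_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        X = self._validate(X, d)
        pts = X.reshape(X.shape[0], -1, d).copy()
        pts -= pts.mean(axis=1, keepdims=True)
        self.d_ = d
        if self.mode == "center_only":
            self.mean_shape_ = pts.mean(axis=0)
            self.n_iter_ = 0
            return pts.reshape(X.shape[0], -1)

        pts = np.stack([p / mean_centroid_distance(p) for p in pts])
        # initialize from the permutation-invariant raw mean so row order
        # cannot change the final orientation
        mean = pts.mean(axis=0)
        mean -= mean.mean(axis=0)
        mean /= mean_centroid_distance(mean)
        self.n_iter_ = 0
        for it in range(1, self.max_iter + 1):
            self.n_iter_ = it
            # scale first, then rotate each shape onto the current mean
            for i in range(pts.shape[0]):
                p = pts[i] / mean_centroid_distance(pts[i])
                pts[i] = p @ optimal_rotation(p, mean)
            new_mean = pts.mean(axis=0)
            new_mean -= new_mean.mean(axis=0)
            new_mean /= mean_centroid_distance(new_mean)
            # remove the free global rotation of the consensus, otherwise the
            # whole configuration drifts and convergence is artificially slow
            new_mean = new_mean @ optimal_rotation(new_mean, mean)
            move = np.sqrt(np.mean((new_mean - mean) ** 2))
            mean = new_mean
            if move < self.tol:
                break
        # final pass: align to the converged consensus, every shape at exactly
        # unit mean point-to-centroid distance
        for i in range(pts.shape[0]):
            p = pts[i] @ optimal_rotation(pts[i], mean)
            pts[i] = p / mean_centroid_distance(p)
        self.mean_shape_ = mean
        return pts.reshape(X.shape[0], -1)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Align new shapes to the fitted consensus (no refit of the mean)."""
        if not hasattr(self, "mean_shape_"):
            raise ValueError("GeneralizedProcrustes instance is not fitted yet")
        X = self._validate(X, self.d_)
        pts = X.reshape(X.shape[0], -1, self.d_).copy()
        pts -= pts.mean(axis=1, keepdims=True)
        if self.mode == "center_only":
            return pts.reshape(X.shape[0], -1)
        for i in range(pts.shape[0]):
            p = pts[i] / mean_centroid_distance(pts[i])
            p = p @ optimal_rotation(p, self.mean_shape_)
            pts[i] = p / mean_centroid_distance(p)
        return pts.reshape(X.shape[0], -1)


def preprocess_dataset(dataset: ShapeDataset, mode: str = "full",
                       tol: float = 1e-9, max_iter: int = 100) -> ShapeDataset:
    """Preprocess every shape in a dataset.

    ``mode="full"``: generalized Procrustes with centering, rotation, and unit
    point-to-centroid scaling.  ``mode="center_only"``: centering only.
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    gpa = GeneralizedProcrustes(mode=mode, tol=tol, max_iter=max_iter)
    X = gpa.fit_transform(dataset.X, d=dataset.d)
    return dataset.with_vectors(X)
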