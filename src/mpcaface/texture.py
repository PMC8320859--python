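"""Image texture vectorization for appearance eigenmodels.

"Texture" is the pattern of grayscale intensities inside a fixed region of
interest (ROI), flattened into a vector in a deterministic (row-major) pixel
order so it can feed the same PCA / mPCA machinery as shape vectors.
Per-image illumination is standardized by an affine rescale of the ROI
intensities to a common mean and standard deviation; a mean-only variant is
available.  No shape-normalizing warp is applied before sampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np


@dataclass(frozen=True)
class RoiMask:
    """Binary raster mask with a deterministic row-major pixel ordering."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, bool)
        if m.ndim != 2:
            raise ValueError("mask must be a 2D raster")
        if not m.any():
            raise ValueError("mask must contain at least one true pixel")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Row-major flat indices of the true pixels."""
        return np.flatnonzero(self.mask.ravel())

    @classmethod
    def from_png(cls, path: str | Path) -> "RoiMask":
        """Nonzero pixels of a grayscale PNG are inside the ROI."""
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:
            img = img[..., 0]
        return cls(img != 0)

    @classmethod
    def from_polygon_json(cls, path: str | Path) -> "RoiMask":
        """Rasterize ``{"height": H, "width": W, "polygon": [[x, y], ...]}``.

        Filled by scanline over pixel centers (skimage.draw.polygon).
        """
        from skimage.draw import polygon as draw_polygon

        spec = json.loads(Path(path).read_text())
        h, w = int(spec["height"]), int(spec["width"])
        pts = np.asarray(spec["polygon"], float)
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=(h, w))
        mask = np.zeros((h, w), bool)
        mask[rr, cc] = True
        return cls(mask)


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF and promote to float in [0, 1]."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    return img.astype(float)


def extract_texture(image: np.ndarray, roi: RoiMask) -> np.ndarray:
    """Intensities of the ROI pixels in mask order, as floats."""
    image = np.asarray(image, float)
    if image.shape != roi.shape:
        raise ValueError(
            f"image shape {image.shape} does not match mask shape {roi.shape}"
        )
    return image.ravel()[roi.flat_indices].copy()


def standardize_illumination(
    vector: np.ndarray,
    target_mean: float = 0.0,
    target_sd: float = 1.0,
    mean_only: bool = False,
) -> np.ndarray:
    """Affine rescale of a texture vector to a common mean (and SD).

    A zero-variance vector is mean-shifted only, with a warning.
    ``mean_only=True`` shifts the mean without touching the scale.
    """
    v = np.asarray(vector, float)
    mean = v.mean()
    if mean_only:
        return v - mean + target_mean
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd <= 0:
        warnings.warn("zero-variance texture vector; applying mean shift only")
        return v - mean + target_mean
    return (v - mean) / sd * target_sd + target_mean


def render_texture(vector: np.ndarray, roi: RoiMask, background: float = 0.0) -> np.ndarray:
    """Scatter a texture vector back into the mask positions."""
    v = np.asarray(vector, float)
    if v.size != roi.n_pixels:
        raise ValueError(
            f"vector length {v.size} does not match ROI pixel count {roi.n_pixels}"
        )
    out = np.full(roi.shape[0] * roi.shape[1], float(background))
    out[roi.flat_indices] = v
    return out.reshape(roi.shape)


def render_mode_image(model, l: int, c: float, roi: RoiMask,
                      level: int | None = None, background: float = 0.0) -> np.ndarray:
    """Image of ``mean + c * sqrt(lambda_l) * u_l`` inside the ROI.

    ``model`` is a fitted single-level eigenmodel, or a fitted multilevel
    model with ``level`` (0 = top) selecting which level's mode to render.
    """
    if level is None:
        vec = model.mode_of_variation(l, c)
    else:
        vals = model.eigenvalues_[level]
        comps = model.components_[level]
        if not 0 <= l < comps.shape[0]:
            raise ValueError(f"component index {l} out of range at level {level}")
        vec = model.grand_mean_ + c * np.sqrt(vals[l]) * comps[l]
    return render_texture(vec, roi, background)


class IlluminationStandardizer:
    """Transformer applying :func:`standardize_illumination` row-wise."""

    def __init__(self, target_mean: float = 0.0, target_sd: float = 1.0,
                 mean_only: bool = False):
        self.target_mean = target_mean
        self.target_sd = target_sd
        self.mean_only = mean_only

    def get_params(self, deep=True):
        return {"target_mean": self.target_mean, "target_sd": self.target_sd,
                "mean_only": self.mean_only}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        return np.stack([
            standardize_illumination(row, self.target_mean, self.target_sd,
                                     self.mean_only)
            for row in X
        ])

    def fit_transform(self, X, y=None):
        return self.transform(X)
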