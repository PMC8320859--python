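"""Landmark configurations, shape datasets, and the landmark CSV dialect.

A *shape* is an ordered configuration of ``k`` labeled points in ``d``
dimensions (``d`` in {2, 3}).  Datasets carry one flattened shape vector per
observation plus a hierarchical label record (group / subject / condition /
optional frame index), which is what the multilevel model consumes.

Shape vectors use an interleaved layout: ``(x1, y1[, z1], x2, y2[, z2], ...)``
— i.e. row-major flattening of the ``(k, d)`` point array — so point-wise
operations stay local in the vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LABEL_COLUMNS = ["dataset_id", "group_id", "subject_id", "condition_id", "frame_index"]
_COORD_COLUMNS = {2: ["x", "y"], 3: ["x", "y", "z"]}


@dataclass
class LandmarkShape:
    """One configuration of ``k`` labeled points in 2 or 3 dimensions."""

    points: np.ndarray
    landmark_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise ValueError(
                f"points must be (k, d) with d in {{2, 3}}, got {self.points.shape}"
            )
        if self.points.shape[0] < 3:
            raise ValueError("a shape needs at least 3 landmarks")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("all coordinates must be finite")
        if self.landmark_names is not None and len(self.landmark_names) != self.k:
            raise ValueError("landmark_names length must equal the landmark count")

    @property
    def k(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def to_vector(self) -> np.ndarray:
        """Flatten to the interleaved ``(x1, y1[, z1], x2, ...)`` layout."""
        return self.points.reshape(-1).copy()

    @classmethod
    def from_vector(
        cls,
        values: np.ndarray,
        d: int,
        landmark_names: Sequence[str] | None = None,
    ) -> "LandmarkShape":
        values = np.asarray(values, dtype=float)
        if values.size % d:
            raise ValueError(f"vector length {values.size} not divisible by d={d}")
        return cls(values.reshape(-1, d), landmark_names)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ShapeDataset:
    """Flattened shape vectors plus per-observation hierarchical labels.

    ``X`` is ``(n_obs, k * d)``; ``labels`` is a DataFrame with the columns in
    :data:`LABEL_COLUMNS`, one row per observation, aligned with ``X``.
    """

    X: np.ndarray
    labels: pd.DataFrame
    d: int
    landmark_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels must have one row per shape vector")
        if self.X.shape[1] % self.d:
            raise ValueError("vector length not divisible by dimension")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"label record incomplete, missing columns: {missing}")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1] // self.d

    def shape(self, i: int) -> LandmarkShape:
        return LandmarkShape.from_vector(self.X[i], self.d, self.landmark_names)

    def shapes(self) -> list[LandmarkShape]:
        return [self.shape(i) for i in range(self.n)]

    def with_vectors(self, X: np.ndarray) -> "ShapeDataset":
        """Copy of the dataset with the coordinate matrix replaced."""
        return ShapeDataset(np.asarray(X, float), self.labels.copy(), self.d, self.landmark_names)


def read_landmarks(path: str | Path, dimension: int) -> ShapeDataset:
    """Read a landmark CSV into a :class:`ShapeDataset`.

    The dialect has one landmark per row with header
    ``dataset_id,group_id,subject_id,condition_id,frame_index,landmark,x,y[,z]``.
    Consecutive rows sharing the same label record form one shape; shapes are
    returned in file order.  Raises :class:`ValueError` for ragged landmark
    counts (naming the offending record) or non-numeric coordinates (naming
    the row number).
    """
    if dimension not in (2, 3):
        raise ValueError("dimension must be 2 or 3")
    coords = _COORD_COLUMNS[dimension]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = LABEL_COLUMNS + ["landmark"] + coords
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    values = np.empty((len(df), dimension))
    for j, c in enumerate(coords):
        for i, raw in enumerate(df[c].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                # +2: one for the header line, one for 0-based indexing
                raise ValueError(
                    f"{path}: non-numeric coordinate {c}={raw!r} at row {i + 2}"
                ) from None

    key = df[LABEL_COLUMNS].agg(tuple, axis=1)
    block_id = (key != key.shift()).cumsum()
    vectors, label_rows, names = [], [], None
    k_expected = None
    for _, block in df.groupby(block_id, sort=False):
        idx = block.index.to_numpy()
        k = len(idx)
        if k_expected is None:
            k_expected = k
            names = list(block["landmark"])
        elif k != k_expected:
            rec = tuple(block.iloc[0][LABEL_COLUMNS])
            raise ValueError(
                f"{path}: record {rec} has {k} landmarks, expected {k_expected}"
            )
        vectors.append(values[idx].reshape(-1))
        label_rows.append(block.iloc[0][LABEL_COLUMNS])

    if not vectors:
        raise ValueError(f"{path}: no landmark rows")
    labels = pd.DataFrame(label_rows).reset_index(drop=True)
    return ShapeDataset(np.vstack(vectors), labels, dimension, names)


def write_landmarks(dataset: ShapeDataset, path: str | Path) -> None:
    """Write a dataset in the same CSV dialect that :func:`read_landmarks` reads."""
    coords = _COORD_COLUMNS[dataset.d]
    names = list(dataset.landmark_names) if dataset.landmark_names else [
        f"p{i + 1}" for i in range(dataset.k)
    ]
    rows = []
    for i in range(dataset.n):
        pts = dataset.X[i].reshape(-1, dataset.d)
        lab = dataset.labels.iloc[i]
        for name, p in zip(names, pts):
            row = {c: lab[c] for c in LABEL_COLUMNS}
            row["landmark"] = name
            row.update({c: repr(float(v)) for c, v in zip(coords, p)})
            rows.append(row)
    pd.DataFrame(rows, columns=LABEL_COLUMNS + ["landmark"] + coords).to_csv(
        path, index=False
    )
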