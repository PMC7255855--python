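"""Batch-trained self-organizing map on a fixed rectangular grid.

The classic landmark generator: a ``width x height`` lattice of codebook
vectors trained by whole-dataset (batch) epochs.  Each epoch assigns every
point to its best-matching unit (BMU) and moves every codebook vector to the
Gaussian-neighborhood-weighted mean of the assigned points.  The trained
codebook provides the high-dimensional landmarks; the integer grid positions
provide the low-dimensional ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import LandmarkModel, PointCloud, ValidationError

__all__ = ["SomGrid", "init_codebook", "bmu", "batch_epoch", "train_som", "model_from_som"]


@dataclass
class SomGrid:
    """A rectangular SOM: codebook vectors plus their integer grid positions.

    ``coords`` enumerates the lattice ``{0..width-1} x {0..height-1}`` in
    row-major order (x fastest); unit spacing of the grid directly defines
    the geometry of the low-dimensional landmarks.
    """

    width: int
    height: int
    codebook: np.ndarray

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=np.float64)
        if self.codebook.shape[0] != self.width * self.height:
            raise ValidationError(
                f"codebook has {self.codebook.shape[0]} rows, expected "
                f"{self.width * self.height} for a {self.width}x{self.height} grid"
            )

    @property
    def coords(self) -> np.ndarray:
        xs, ys = np.meshgrid(np.arange(self.width), np.arange(self.height))
        return np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)


def _points(points: PointCloud | np.ndarray) -> np.ndarray:
    return points.values if isinstance(points, PointCloud) else np.asarray(points, dtype=np.float64)


def init_codebook(
    points: PointCloud | np.ndarray, width: int, height: int, seed: int | None = 0
) -> SomGrid:
    """Seed the codebook with a random sample of data rows (reproducible).

    Sampling is without replacement; if the grid is larger than the dataset
    the sample falls back to replacement with a warning.
    """
    X = _points(points)
    n_units = width * height
    rng = np.random.default_rng(seed)
    if n_units > X.shape[0]:
        warnings.warn(
            f"grid has {n_units} units but only {X.shape[0]} data rows; "
            "sampling with replacement",
            stacklevel=2,
        )
        idx = rng.integers(0, X.shape[0], size=n_units)
    else:
        idx = rng.choice(X.shape[0], size=n_units, replace=False)
    return SomGrid(width=width, height=height, codebook=X[idx].copy())


def bmu(x, grid: SomGrid) -> int:
    """Index of the best-matching unit (nearest codebook row; ties -> lowest)."""
    x = np.asarray(x, dtype=np.float64)
    d = ((grid.codebook - x) ** 2).sum(axis=1)
    return int(np.argmin(d))


def _bmus(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Vectorized BMU assignment (squared-distance argmin, ties -> lowest)."""
    # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2; ||x||^2 is constant per row
    csq = (codebook**2).sum(axis=1)[None, :]
    out = np.empty(X.shape[0], dtype=np.intp)
    step = max(1, 2**22 // max(1, codebook.shape[0]))  # bound scratch memory
    for s in range(0, X.shape[0], step):
        d = X[s : s + step] @ codebook.T
        d *= -2.0
        d += csq
        out[s : s + step] = np.argmin(d, axis=1)
    return out


def _kernel(coords: np.ndarray, radius: float) -> np.ndarray:
    """Gaussian neighborhood kernel on grid coordinates; radius 0 = identity."""
    if radius <= 0:
        return np.eye(coords.shape[0])
    diff = coords[:, None, :] - coords[None, :, :]
    sq = (diff**2).sum(axis=-1)
    return np.exp(-sq / (2.0 * radius * radius))


def batch_epoch(
    points: PointCloud | np.ndarray, grid: SomGrid, radius: float
) -> SomGrid:
    """One batch update: move each unit to the kernel-weighted mean of points.

    The new codebook row ``j`` is the mean of all points, weighted by the
    Gaussian kernel between each point's BMU grid position and ``j``'s grid
    position.  Units receiving zero kernel mass keep their previous vector.
    At ``radius -> 0`` the kernel is the same-unit indicator and the epoch
    reduces to one Lloyd (k-means) step.
    """
    X = _points(points)
    if X.shape[0] == 0:
        return SomGrid(grid.width, grid.height, grid.codebook.copy())
    n_units = grid.codebook.shape[0]
    assign = _bmus(X, grid.codebook)
    counts = np.bincount(assign, minlength=n_units).astype(np.float64)
    sums = np.zeros_like(grid.codebook)
    np.add.at(sums, assign, X)

    K = _kernel(grid.coords, radius)
    num = K @ sums
    den = K @ counts
    new = grid.codebook.copy()
    mask = den > 0
    new[mask] = num[mask] / den[mask, None]
    return SomGrid(grid.width, grid.height, new)


def train_som(
    points: PointCloud | np.ndarray,
    width: int = 10,
    height: int = 10,
    epochs: int = 10,
    radius_start: float | None = None,
    radius_end: float = 0.5,
    seed: int | None = 0,
) -> SomGrid:
    """Train a batch SOM: seeded init, then ``epochs`` batch updates with the
    neighborhood radius shrinking linearly from ``radius_start`` (default
    half the larger grid side) to ``radius_end``."""
    if epochs < 1:
        raise ValidationError("epochs must be >= 1")
    if radius_start is None:
        radius_start = max(width, height) / 2.0
    grid = init_codebook(points, width, height, seed)
    radii = np.linspace(radius_start, radius_end, epochs)
    for r in radii:
        grid = batch_epoch(points, grid, float(r))
    return grid


def model_from_som(grid: SomGrid, meta: dict | None = None) -> LandmarkModel:
    """Turn a trained grid into a landmark model: codebook rows become the
    high-dimensional landmarks, grid positions the low-dimensional ones."""
    m = {"generator": "som", "width": grid.width, "height": grid.height}
    if meta:
        m.update(meta)
    return LandmarkModel(high=grid.codebook.copy(), low=grid.coords, meta=m)
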