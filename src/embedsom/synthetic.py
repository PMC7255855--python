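"""Seeded synthetic point clouds for testing and demonstration.

The generators emulate the coarse structure of cytometry expression data
that the embedding targets — well-separated populations, a dominant
population with a rare satellite, and noisy planar manifolds — without any
download.  Labels and ground-truth coordinates are returned strictly for
evaluation; nothing downstream trains on them.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import PointCloud, ValidationError

__all__ = ["gaussian_mixture", "rare_population_set", "planar_manifold"]


def gaussian_mixture(
    n: int,
    centers: Sequence[Sequence[float]],
    sds: Sequence[float] | float = 1.0,
    proportions: Sequence[float] | None = None,
    seed: int | None = 0,
) -> tuple[PointCloud, np.ndarray]:
    """Sample ``n`` points from a mixture of isotropic Gaussians.

    Returns the cloud and the integer component label of each point.
    """
    centers = np.asarray(centers, dtype=np.float64)
    if centers.ndim != 2:
        raise ValidationError("centers must be a list of D-vectors")
    g = centers.shape[0]
    sds = np.broadcast_to(np.asarray(sds, dtype=np.float64), (g,))
    if proportions is None:
        proportions = np.full(g, 1.0 / g)
    else:
        proportions = np.asarray(proportions, dtype=np.float64)
        if proportions.shape != (g,):
            raise ValidationError("one proportion per center required")
        if not np.isclose(proportions.sum(), 1.0):
            raise ValidationError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(g, size=n, p=proportions)
    X = centers[labels] + rng.standard_normal((n, centers.shape[1])) * sds[labels][:, None]
    return PointCloud(X), labels


def rare_population_set(
    n: int,
    rare_fraction: float = 0.01,
    separation: float = 5.0,
    D: int = 5,
    seed: int | None = 0,
) -> tuple[PointCloud, np.ndarray]:
    """A dominant unit-variance blob plus one small satellite blob.

    The satellite center sits ``separation`` standard deviations away along
    the first axis; label 1 marks the rare points.
    """
    if not 0 < rare_fraction < 0.5:
        raise ValidationError("rare_fraction must lie in (0, 0.5)")
    centers = np.zeros((2, D))
    centers[1, 0] = separation
    return gaussian_mixture(
        n, centers, sds=1.0, proportions=[1.0 - rare_fraction, rare_fraction], seed=seed
    )


def planar_manifold(
    n: int, D: int = 5, noise_sd: float = 0.0, seed: int | None = 0
) -> tuple[PointCloud, np.ndarray]:
    """Points on a random 2-D plane isometrically embedded in ``D``-space,
    plus isotropic Gaussian noise; returns the cloud and the true planar
    coordinates (for Procrustes-style evaluation)."""
    if D < 2:
        raise ValidationError("D must be >= 2")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-1.0, 1.0, size=(n, 2))
    # random 2-frame in R^D: orthonormal columns from a QR decomposition
    basis, _ = np.linalg.qr(rng.standard_normal((D, 2)))
    X = coords @ basis.T
    if noise_sd > 0:
        X = X + rng.standard_normal((n, D)) * noise_sd
    return PointCloud(X), coords
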