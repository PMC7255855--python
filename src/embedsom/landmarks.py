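"""Generalized landmark adapters.

The projection only needs *some* pairing of high- and low-dimensional
landmarks; besides SOM grids, a small random sample of the data points can
serve as the high-dimensional landmarks, with their low-dimensional layout
supplied by any external method (t-SNE, UMAP, PCA, hand placement).  This
module builds :class:`~embedsom.core.LandmarkModel` objects from such
pairings; it never runs a dimensionality reduction itself.
"""

from __future__ import annotations

import numpy as np

from .core import LandmarkModel, PointCloud, ValidationError
from .som import _points

__all__ = ["random_landmarks", "attach_low"]


def random_landmarks(
    points: PointCloud | np.ndarray, count: int, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of ``count`` data rows (without replacement) to use as
    high-dimensional landmarks; returns ``(rows, chosen_indices)``."""
    X = _points(points)
    if count < 4:
        raise ValidationError("need at least 4 landmarks")
    if count > X.shape[0]:
        raise ValidationError(
            f"cannot sample {count} landmarks from {X.shape[0]} points"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(X.shape[0], size=count, replace=False)
    return X[idx].copy(), idx


def attach_low(high: np.ndarray, low: np.ndarray, meta: dict | None = None) -> LandmarkModel:
    """Pair high-dimensional landmarks with externally computed low
    coordinates (any P >= 1) and validate the result."""
    model = LandmarkModel(
        high=np.asarray(high, dtype=np.float64),
        low=np.asarray(low, dtype=np.float64),
        meta={"generator": "external", **(meta or {})},
    )
    return model.validate()
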