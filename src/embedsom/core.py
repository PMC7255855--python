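"""Shared domain types, parameter defaults and validation.

The central object is the :class:`LandmarkModel`: a paired set of landmarks
``high`` (``n_L x D``, positions in the input space) and ``low`` (``n_L x P``,
positions in the embedding space).  Any generator that produces such a pairing
— a batch SOM grid, a growing quadtree SOM, or a random sample of points laid
out by an external method — can drive the projection.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "PointCloud",
    "LandmarkModel",
    "EmbedParams",
    "NeighborScores",
    "default_params",
    "validate_model",
    "METRICS",
]

#: Distance measures accepted for landmark scoring.  Only the scoring step
#: uses them; the affine projections are always dot products.
METRICS = ("euclidean", "L1", "Linf")


class ValidationError(ValueError):
    """Raised when inputs violate a model or parameter invariant."""


def _as_matrix(values: Any, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class PointCloud:
    """An ``n x D`` matrix of points (cells), one row per observation.

    Entries must be finite; units are arbitrary (typically asinh-transformed
    marker intensities).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_matrix(self.values, "points")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("point matrix contains NaN or infinite entries")
        if arr.shape[1] < 1:
            raise ValidationError("points must have at least one column")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class LandmarkModel:
    """Paired high- and low-dimensional landmarks.

    Parameters
    ----------
    high : array, shape (n_L, D)
        Landmark positions in the input space.
    low : array, shape (n_L, P)
        Corresponding positions in the embedding space (P defaults to 2).
    meta : dict
        Provenance (generator name, seed, training parameters, per-landmark
        quadtree levels where applicable).  Carried through serialization.
    """

    high: np.ndarray
    low: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.high = _as_matrix(self.high, "high landmarks")
        self.low = _as_matrix(self.low, "low landmarks")

    @property
    def n_landmarks(self) -> int:
        return self.high.shape[0]

    @property
    def dim(self) -> int:
        return self.high.shape[1]

    @property
    def out_dim(self) -> int:
        return self.low.shape[1]

    def validate(self) -> "LandmarkModel":
        if self.high.shape[0] != self.low.shape[0]:
            raise ValidationError(
                f"high has {self.high.shape[0]} rows but low has "
                f"{self.low.shape[0]}; landmark pairing requires equal counts"
            )
        if not np.all(np.isfinite(self.high)):
            raise ValidationError("high landmark matrix contains NaN/Inf")
        if not np.all(np.isfinite(self.low)):
            raise ValidationError("low landmark matrix contains NaN/Inf")
        if self.n_landmarks < 4:
            raise ValidationError(
                f"need at least 4 landmarks, got {self.n_landmarks}"
            )
        if not np.any(np.ptp(self.high, axis=0) > 0):
            raise ValidationError("all high-dimensional landmarks are identical")
        return self

    # -- serialization -------------------------------------------------
    # JSON floats round-trip bit-exactly in Python (shortest-repr encoding),
    # which gives the required exact model round-trip in a text format.

    def to_dict(self) -> dict:
        return {
            "format": "embedsom-landmark-model",
            "version": 1,
            "n_landmarks": self.n_landmarks,
            "dim": self.dim,
            "out_dim": self.out_dim,
            "high": self.high.tolist(),
            "low": self.low.tolist(),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkModel":
        if d.get("format") != "embedsom-landmark-model":
            raise ValidationError("not a landmark model file")
        return cls(
            high=np.array(d["high"], dtype=np.float64),
            low=np.array(d["low"], dtype=np.float64),
            meta=d.get("meta", {}),
        )

    def save(self, path: str | os.PathLike) -> None:
        """Write the model as JSON, atomically (temp file then rename)."""
        path = os.fspath(path)
        payload = json.dumps(self.to_dict(), indent=1)
        fd, tmp = tempfile.mkstemp(
            dir=os.path.dirname(os.path.abspath(path)) or ".", suffix=".tmp"
        )
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @classmethod
    def load(cls, path: str | os.PathLike) -> "LandmarkModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class EmbedParams:
    """Tunable parameters of the projection.

    ``k`` — number of nearest landmarks used per point (4 ≤ k ≤ n_L).
    ``m`` — steepness of score decay as landmark distance approaches the
    k-th nearest; larger m keeps more of the neighborhood active.
    ``b`` — decay steepness for landmarks far from the point, relative to
    the local distance distribution.
    ``a`` — penalty exponent on the low-space distance of a landmark pair;
    down-weights pairs of mutually distant low-dimensional landmarks.
    ``metric`` — distance used for landmark *scoring* only.
    """

    k: int = 10
    m: float = 10.0
    b: float = 1.0 / np.e
    a: float = 1.0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValidationError(f"k must be at least 4, got {self.k}")
        if not self.m > 0:
            raise ValidationError(f"m must be positive, got {self.m}")
        if self.b < 0:
            raise ValidationError(f"b must be nonnegative, got {self.b}")
        if self.a < 0:
            raise ValidationError(f"a must be nonnegative, got {self.a}")
        if self.metric not in METRICS:
            raise ValidationError(
                f"unknown metric {self.metric!r}; choose one of {METRICS}"
            )


@dataclass(frozen=True)
class NeighborScores:
    """Per-point nearest-landmark state: indices, distances, and scores.

    ``order`` holds the indices of the k nearest landmarks in ascending
    distance; ``dists`` the matching (metric) distances; ``mu``/``sigma``
    the location/scale estimate of that local distance distribution; and
    ``scores`` the resulting weights S_1..S_k with S_k = 0 exactly.
    """

    order: np.ndarray
    dists: np.ndarray
    mu: float
    sigma: float
    scores: np.ndarray


def default_params(n_landmarks: int, metric: str = "euclidean") -> EmbedParams:
    """Default projection parameters for a model with ``n_landmarks``.

    ``k`` scales as the square root of the landmark count (floored at 4 and
    capped at the landmark count), keeping the per-point cost linear in the
    landmark count; ``m = 10``, ``b = 1/e`` and ``a = 1``.
    """
    if n_landmarks < 4:
        raise ValidationError(
            f"a usable model needs at least 4 landmarks, got {n_landmarks}"
        )
    k = int(np.clip(round(np.sqrt(n_landmarks)), 4, n_landmarks))
    return EmbedParams(k=k, m=10.0, b=1.0 / np.e, a=1.0, metric=metric)


def validate_model(model: LandmarkModel, params: EmbedParams | None = None) -> LandmarkModel:
    """Check all model invariants (and ``k <= n_L`` if params are given).

    Returns the model unchanged; raises :class:`ValidationError` with a
    descriptive message otherwise.
    """
    model.validate()
    if params is not None and params.k > model.n_landmarks:
        raise ValidationError(
            f"k={params.k} exceeds the number of landmarks ({model.n_landmarks})"
        )
    return model
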