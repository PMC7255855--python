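"""Landmark-directed embedding of points into a low-dimensional space.

Given a :class:`~embedsom.core.LandmarkModel` (paired landmarks ``L`` in the
input space and ``l`` in the output space), every point ``X`` is embedded
independently:

1. find the ``k`` nearest landmarks of ``X`` and convert their distances to
   scores ``S`` that decay smoothly to exactly zero at the k-th neighbor;
2. for every unordered pair among the ``k-1`` closest landmarks, project
   ``X`` onto the affine line through the pair in the input space, giving a
   scalar coordinate ``d``;
3. accumulate, per pair, the linear equation asking that the output point
   project to the same ``d`` on the corresponding low-space line, weighted by
   the pair score;
4. solve the resulting small (P x P) least-squares normal system.

The zero score of the k-th neighbor makes the map smooth in ``X`` even where
the nearest-neighbor set changes; the per-point independence makes the whole
embedding trivially parallel and deterministic.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from typing import Sequence

import numpy as np

from .core import (
    EmbedParams,
    LandmarkModel,
    NeighborScores,
    PointCloud,
    ValidationError,
    validate_model,
)

__all__ = [
    "DegeneratePointError",
    "SingularSystemError",
    "landmark_distances",
    "neighbor_scores",
    "embed_point",
    "embed",
]

#: Relative threshold below which a landmark pair is considered duplicated
#: (zero separation in input or output space) and skipped.
EPS_H = 1e-12
#: Relative threshold on the system determinant below which the accumulated
#: linear system is reported as singular.
EPS_DET = 1e-12

#: Points are processed in fixed-size blocks; the block boundaries do not
#: depend on the thread count, so results are bitwise reproducible for any
#: degree of parallelism.
_BLOCK = 256


class DegeneratePointError(ValueError):
    """A point coincides with at least ``k`` landmarks (all scoring
    distances zero); the embedding falls back to the first matching
    landmark's low coordinates."""


class SingularSystemError(np.linalg.LinAlgError):
    """The accumulated projection system is (near-)singular.

    Usually caused by too few non-negligible pair scores; increasing ``k``
    or ``m`` (or lowering ``b``) enlarges the active neighborhood and
    resolves it.
    """


def _block_distances(X: np.ndarray, high: np.ndarray, metric: str) -> np.ndarray:
    """Scoring distances from each row of X to each landmark.

    Euclidean distances are returned *squared* (the algorithm consumes the
    squared norm directly); L1/Linf are the plain metric values.
    """
    if X.shape[1] != high.shape[1]:
        raise ValidationError(
            f"point dimension {X.shape[1]} does not match landmark "
            f"dimension {high.shape[1]}"
        )
    diff = X[:, None, :] - high[None, :, :]
    if metric == "euclidean":
        return np.einsum("ijk,ijk->ij", diff, diff)
    if metric == "L1":
        return np.abs(diff).sum(axis=-1)
    if metric == "Linf":
        return np.abs(diff).max(axis=-1)
    raise ValidationError(f"unknown metric {metric!r}")


def landmark_distances(x: Sequence[float], high: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Distances from one point to all landmarks (squared for Euclidean)."""
    x = np.asarray(x, dtype=np.float64).reshape(1, -1)
    return _block_distances(x, np.asarray(high, dtype=np.float64), metric)[0]


def _block_scores(
    c: np.ndarray, k: int, m: float, b: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized neighbor ordering and scoring for a block of points.

    Returns (order, dists, mu, sigma, scores); rows whose k-th neighbor
    distance is zero are degenerate and carry NaN scores (resolved by the
    caller).
    """
    if k > c.shape[1]:
        raise ValidationError(f"k={k} exceeds the number of landmarks ({c.shape[1]})")
    # Full stable sort: ties resolve to the lowest landmark index.
    order = np.argsort(c, axis=1, kind="stable")[:, :k]
    dists = np.take_along_axis(c, order, axis=1)
    ck = dists[:, -1]

    # Location/scale of the local distance distribution, harmonically
    # weighted to emphasize the nearest landmarks.
    w = 1.0 / np.arange(1, k + 1)
    wsum = w.sum()
    mu = (dists * w).sum(axis=1) / wsum
    var = (w * (dists - mu[:, None]) ** 2).sum(axis=1) / wsum
    sigma = np.sqrt(var)

    # exp(b (mu - c_i) / sigma); a zero sigma (all k distances equal) makes
    # the factor 1 for every neighbor.
    safe_sigma = np.where(sigma > 0, sigma, 1.0)
    far = np.exp(b * (mu[:, None] - dists) / safe_sigma[:, None])
    far = np.where(sigma[:, None] > 0, far, 1.0)

    safe_ck = np.where(ck > 0, ck, 1.0)
    near = 1.0 - np.exp((dists - ck[:, None]) / (m * safe_ck[:, None]))
    scores = far * near
    scores[ck == 0] = np.nan  # degenerate rows, handled by the caller
    return order, dists, mu, sigma, scores


def neighbor_scores(c: Sequence[float], k: int, m: float, b: float) -> NeighborScores:
    """Score the ``k`` nearest landmarks of one point from its distances.

    The score of the k-th neighbor is exactly zero, which is what makes the
    embedding continuous across changes of the nearest-neighbor set.

    Raises
    ------
    DegeneratePointError
        If the k-th smallest distance is zero (the point coincides with at
        least ``k`` landmarks); the caller should fall back to the low
        coordinates of the first zero-distance landmark.
    """
    c = np.asarray(c, dtype=np.float64).reshape(1, -1)
    order, dists, mu, sigma, scores = _block_scores(c, k, m, b)
    if dists[0, -1] == 0:
        raise DegeneratePointError(
            f"point coincides with at least {k} landmarks (k-th neighbor "
            "distance is zero)"
        )
    return NeighborScores(
        order=order[0], dists=dists[0], mu=float(mu[0]), sigma=float(sigma[0]),
        scores=scores[0],
    )


def _solve_cramer2(A: np.ndarray, rhs: np.ndarray, eps_det: float, offset: int) -> np.ndarray:
    a, bb, d = A[:, 0, 0], A[:, 0, 1], A[:, 1, 1]
    det = a * d - bb * bb
    scale = ((a + d) * 0.5) ** 2
    bad = ~(np.abs(det) > eps_det * scale)
    if np.any(bad):
        _raise_singular(bad, offset)
    out = np.empty_like(rhs)
    out[:, 0] = (rhs[:, 0] * d - rhs[:, 1] * bb) / det
    out[:, 1] = (a * rhs[:, 1] - bb * rhs[:, 0]) / det
    return out


def _solve_cramer3(A: np.ndarray, rhs: np.ndarray, eps_det: float, offset: int) -> np.ndarray:
    det = np.linalg.det(A)
    scale = (np.trace(A, axis1=1, axis2=2) / 3.0) ** 3
    bad = ~(np.abs(det) > eps_det * np.abs(scale))
    if np.any(bad):
        _raise_singular(bad, offset)
    out = np.empty_like(rhs)
    for p in range(3):
        Ap = A.copy()
        Ap[:, :, p] = rhs
        out[:, p] = np.linalg.det(Ap) / det
    return out


def _raise_singular(bad: np.ndarray, offset: int) -> None:
    row = int(np.flatnonzero(bad)[0]) + offset
    raise SingularSystemError(
        f"projection system is singular for point {row}; too few landmark "
        "pairs carry non-negligible scores — try a larger k or m, or a "
        "smaller b"
    )


def _embed_block(
    X: np.ndarray,
    high: np.ndarray,
    low: np.ndarray,
    params: EmbedParams,
    eps_h: float,
    eps_det: float,
    offset: int = 0,
) -> np.ndarray:
    """Embed one block of points; pure function of its arguments."""
    n, P = X.shape[0], low.shape[1]
    k = params.k
    c = _block_distances(X, high, params.metric)
    order, dists, _, _, S = _block_scores(c, k, params.m, params.b)

    degenerate = dists[:, -1] == 0
    S = np.where(degenerate[:, None], 0.0, S)

    # relative duplicate-pair thresholds, scaled to the landmark spread
    scale_high = max(float(np.max(np.ptp(high, axis=0)) ** 2), 1e-300)
    scale_low = max(float(np.max(np.ptp(low, axis=0)) ** 2), 1e-300)

    A = np.zeros((n, P, P))
    rhs = np.zeros((n, P))
    # Pairs range over the k-1 closest landmarks only; the k-th serves
    # purely as the zero-score boundary of the neighborhood.
    for ia in range(k - 2):
        i = order[:, ia]
        Li, li, Si = high[i], low[i], S[:, ia]
        Xmi = X - Li
        for jb in range(ia + 1, k - 1):
            j = order[:, jb]
            dL = high[j] - Li
            denom = np.einsum("ij,ij->i", dL, dL)
            h = low[j] - li
            hh = np.einsum("ij,ij->i", h, h)
            ok = (denom > eps_h * scale_high) & (hh > eps_h * scale_low)
            denom_s = np.where(ok, denom, 1.0)
            hh_s = np.where(ok, hh, 1.0)
            d = np.einsum("ij,ij->i", Xmi, dL) / denom_s
            y = d + np.einsum("ij,ij->i", h, li) / hh_s
            s = (
                (1.0 + hh) ** (-params.a)
                * np.exp(-((d - 0.5) ** 2))
                * Si
                * S[:, jb]
            )
            s = np.where(ok, s, 0.0)
            A += (s / hh_s)[:, None, None] * (h[:, :, None] * h[:, None, :])
            rhs += (s * y)[:, None] * h

    if np.any(degenerate):
        # avoid tripping the singularity check on degenerate rows
        A[degenerate] = np.eye(P)
        rhs[degenerate] = low[order[degenerate, 0]]

    if P == 2:
        out = _solve_cramer2(A, rhs, eps_det, offset)
    elif P == 3:
        out = _solve_cramer3(A, rhs, eps_det, offset)
    else:
        det = np.linalg.det(A)
        scale = (np.trace(A, axis1=1, axis2=2) / P) ** P
        bad = ~(np.abs(det) > eps_det * np.abs(scale))
        if np.any(bad):
            _raise_singular(bad, offset)
        out = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
    return out


def embed_point(
    x: Sequence[float],
    model: LandmarkModel,
    params: EmbedParams | None = None,
    *,
    eps_h: float = EPS_H,
    eps_det: float = EPS_DET,
) -> np.ndarray:
    """Embed a single point; returns its P-vector of output coordinates."""
    if params is None:
        from .core import default_params

        params = default_params(model.n_landmarks)
    validate_model(model, params)
    x = np.asarray(x, dtype=np.float64).reshape(1, -1)
    return _embed_block(x, model.high, model.low, params, eps_h, eps_det)[0]


def embed(
    points: PointCloud | np.ndarray,
    model: LandmarkModel,
    params: EmbedParams | None = None,
    threads: int | None = None,
    *,
    eps_h: float = EPS_H,
    eps_det: float = EPS_DET,
) -> np.ndarray:
    """Embed every row of ``points``; returns an ``n x P`` matrix.

    Each point is embedded independently (row ``i`` of the result equals
    ``embed_point(points[i])``), so the computation parallelizes trivially;
    ``threads`` sets the worker count (``None``/1 = serial).  Blocks of
    fixed size are dispatched to workers, making the output bitwise
    identical for every thread count.
    """
    if params is None:
        from .core import default_params

        params = default_params(model.n_landmarks)
    validate_model(model, params)
    X = points.values if isinstance(points, PointCloud) else np.asarray(points, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("points must form a 2-D matrix")
    n, P = X.shape[0], model.out_dim
    out = np.empty((n, P))
    if n == 0:
        return out
    if X.shape[1] != model.dim:
        raise ValidationError(
            f"point dimension {X.shape[1]} does not match model dimension {model.dim}"
        )

    starts = range(0, n, _BLOCK)

    def run(s: int) -> None:
        e = min(s + _BLOCK, n)
        out[s:e] = _embed_block(
            X[s:e], model.high, model.low, params, eps_h, eps_det, offset=s
        )

    if threads is None or threads <= 1:
        for s in starts:
            run(s)
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            list(pool.map(run, starts))
    return out
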