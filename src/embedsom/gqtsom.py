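"""Growing QuadTree-structured self-organizing map (GQTSOM).

A SOM variant that grows *inwards*: instead of a fixed lattice, the live
units form the leaves of a quadtree.  A node is addressed by an integer
triple ``(L, x, y)`` — depth and position at that depth — and sits in the
plane at ``((2x+1), (2y+1)) * 2^-L``, the center of its quadtree cell.
Training alternates batch SOM epochs (on the plane coordinates) with growth
steps that split the nodes that moved the most in the input space into four
children, so map resolution concentrates where the data demand it — e.g. on
small or rare cell populations.

Two depth penalties keep deep nodes from overcrowding the map: a depth-L
node's neighborhood kernel volume is scaled by ``4^-L`` during the batch
update (its kernel width by ``2^-L``, matching the ``4^-L`` plane coverage
of its quadtree cell), and its growth priority by ``1/(L+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LandmarkModel, PointCloud, ValidationError
from .som import _bmus, _points

__all__ = [
    "QuadtreeNode",
    "GqtsomState",
    "node_plane_coords",
    "split_node",
    "growth_step",
    "train_gqtsom",
    "model_from_gqtsom",
]


@dataclass(frozen=True)
class QuadtreeNode:
    """A live (leaf) GQTSOM unit: quadtree address, codebook vector, and the
    input-space distance it moved in the latest epoch."""

    level: int
    x: int
    y: int
    weight: np.ndarray
    last_move: float = 0.0


def node_plane_coords(node: QuadtreeNode | tuple[int, int, int]) -> np.ndarray:
    """Plane position of a node: ``((2x+1), (2y+1)) * 2^-L``."""
    if isinstance(node, QuadtreeNode):
        L, x, y = node.level, node.x, node.y
    else:
        L, x, y = node
    s = 2.0 ** (-L)
    return np.array([(2 * x + 1) * s, (2 * y + 1) * s])


@dataclass
class GqtsomState:
    """Live nodes of a (possibly mid-training) GQTSOM, stored columnwise."""

    levels: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    weights: np.ndarray
    last_move: np.ndarray
    initial_side: int
    target_codes: int
    epoch: int = 0
    splits: int = 0

    @property
    def node_count(self) -> int:
        return self.weights.shape[0]

    @property
    def plane_coords(self) -> np.ndarray:
        s = 2.0 ** (-self.levels.astype(np.float64))
        return np.column_stack([(2 * self.xs + 1) * s, (2 * self.ys + 1) * s])

    @property
    def nodes(self) -> list[QuadtreeNode]:
        return [
            QuadtreeNode(
                int(self.levels[i]), int(self.xs[i]), int(self.ys[i]),
                self.weights[i].copy(), float(self.last_move[i]),
            )
            for i in range(self.node_count)
        ]

    def check_invariants(self) -> None:
        assert self.node_count == self.initial_side**2 + 3 * self.splits
        pc = self.plane_coords
        assert len({(float(a), float(b)) for a, b in pc}) == self.node_count, (
            "live nodes must occupy unique plane positions"
        )

    def _find(self, level: int, x: int, y: int) -> int:
        hit = np.flatnonzero((self.levels == level) & (self.xs == x) & (self.ys == y))
        if hit.size == 0:
            raise ValidationError(f"node ({level}, {x}, {y}) is not live")
        return int(hit[0])


def _interp_weights(state: GqtsomState, child_coords: np.ndarray, radius: float) -> np.ndarray:
    """Initial codebook vectors for new children: the training-kernel-weighted
    average of the current live nodes' weights around each child position."""
    pc = state.plane_coords
    d2 = ((pc[None, :, :] - child_coords[:, None, :]) ** 2).sum(axis=-1)
    if radius <= 0:
        w = np.zeros_like(d2)
        w[np.arange(d2.shape[0]), np.argmin(d2, axis=1)] = 1.0
    else:
        w = np.exp(-d2 / (2.0 * radius * radius))
        zero = w.sum(axis=1) == 0  # kernel underflow far from all nodes
        if np.any(zero):
            w[zero, :] = 0.0
            w[zero, np.argmin(d2[zero], axis=1)] = 1.0
    return (w @ state.weights) / w.sum(axis=1)[:, None]


def split_node(
    state: GqtsomState,
    node: QuadtreeNode | tuple[int, int, int],
    neighborhood_radius: float = 1.0,
) -> GqtsomState:
    """Split a live node into its four quadtree children (in place).

    The parent ``(L, x, y)`` is removed and replaced by
    ``(L+1, 2x, 2y)``, ``(L+1, 2x+1, 2y)``, ``(L+1, 2x+1, 2y+1)`` and
    ``(L+1, 2x, 2y+1)``; net node count +3.  Child weights are interpolated
    from the pre-split neighborhood with the current training kernel; their
    ``last_move`` starts at 0.
    """
    if isinstance(node, QuadtreeNode):
        L, x, y = node.level, node.x, node.y
    else:
        L, x, y = node
    idx = state._find(L, x, y)

    cL = L + 1
    cxy = np.array(
        [(2 * x, 2 * y), (2 * x + 1, 2 * y), (2 * x + 1, 2 * y + 1), (2 * x, 2 * y + 1)]
    )
    s = 2.0 ** (-cL)
    child_coords = (2 * cxy + 1) * s
    child_w = _interp_weights(state, child_coords, neighborhood_radius)

    keep = np.arange(state.node_count) != idx
    state.levels = np.concatenate([state.levels[keep], np.full(4, cL, dtype=state.levels.dtype)])
    state.xs = np.concatenate([state.xs[keep], cxy[:, 0]])
    state.ys = np.concatenate([state.ys[keep], cxy[:, 1]])
    state.weights = np.concatenate([state.weights[keep], child_w])
    state.last_move = np.concatenate([state.last_move[keep], np.zeros(4)])
    state.splits += 1
    return state


def growth_step(state: GqtsomState, epochs_remaining: int) -> list[tuple[int, int, int]]:
    """Pick the nodes to split this epoch.

    The node count tracks the straight line from the initial ``g**2`` grid
    to ``target_codes`` over the whole training: this epoch splits just
    enough nodes (``ceil`` of a third of the gap to the line's next point)
    to stay on it, never overshooting the target by more than the split
    arity allows and never splitting more nodes than are live.  Candidates
    are ranked by ``last_move / (L+1)`` (largest first — the depth penalty
    discourages runaway refinement), ties broken by lowest ``(L, x, y)``.
    """
    if epochs_remaining < 1:
        raise ValidationError("epochs_remaining must be >= 1")
    deficit = state.target_codes - state.node_count
    if deficit <= 0:
        return []
    total_epochs = state.epoch + epochs_remaining
    frac = (state.epoch + 1) / total_epochs
    ideal = state.initial_side**2 + frac * (state.target_codes - state.initial_side**2)
    n_split = int(np.ceil(max(ideal - state.node_count, 0.0) / 3.0))
    n_split = min(n_split, int(np.ceil(deficit / 3.0)), state.node_count)
    if n_split <= 0:
        return []
    priority = state.last_move / (state.levels + 1.0)
    order = np.lexsort((state.ys, state.xs, state.levels, -priority))
    chosen = order[:n_split]
    return [
        (int(state.levels[i]), int(state.xs[i]), int(state.ys[i])) for i in chosen
    ]


def _init_state(
    X: np.ndarray, target_codes: int, initial_side: int, seed: int | None
) -> GqtsomState:
    g = initial_side
    rng = np.random.default_rng(seed)
    n_units = g * g
    if n_units > X.shape[0]:
        idx = rng.integers(0, X.shape[0], size=n_units)
    else:
        idx = rng.choice(X.shape[0], size=n_units, replace=False)
    xs, ys = np.meshgrid(np.arange(g), np.arange(g))
    return GqtsomState(
        levels=np.zeros(n_units, dtype=np.int64),
        xs=xs.ravel().astype(np.int64),
        ys=ys.ravel().astype(np.int64),
        weights=X[idx].copy(),
        last_move=np.zeros(n_units),
        initial_side=g,
        target_codes=target_codes,
    )


def _gqtsom_epoch(X: np.ndarray, state: GqtsomState, radius: float) -> None:
    """One depth-weighted batch SOM update on the plane coordinates."""
    assign = _bmus(X, state.weights)
    n_units = state.node_count
    counts = np.bincount(assign, minlength=n_units).astype(np.float64)
    sums = np.zeros_like(state.weights)
    np.add.at(sums, assign, X)

    pc = state.plane_coords
    d2 = ((pc[:, None, :] - pc[None, :, :]) ** 2).sum(axis=-1)
    if radius <= 0:
        W = np.eye(n_units)
    else:
        # depth penalty: a depth-L node's neighborhood kernel volume is
        # scaled by 4^-L (sigma by 2^-L); for a node pair the variances
        # combine geometrically, so var(u,j) = r^2 * 2^-(Lu+Lj).  Deep nodes
        # interact only locally, which lets them specialize to fine detail.
        half = 2.0 ** (-state.levels.astype(np.float64))
        var = (radius * radius) * half[:, None] * half[None, :]
        W = np.exp(-d2 / (2.0 * var))

    num = W.T @ sums
    den = W.T @ counts
    mask = den > 0
    new = state.weights.copy()
    new[mask] = num[mask] / den[mask, None]
    state.last_move = np.sqrt(((new - state.weights) ** 2).sum(axis=1))
    state.weights = new


def train_gqtsom(
    points: PointCloud | np.ndarray,
    target_codes: int = 500,
    epochs: int = 20,
    initial_side: int = 3,
    radius_start: float | None = None,
    radius_end: float = 0.5,
    seed: int | None = 0,
) -> GqtsomState:
    """Train a GQTSOM until the map holds ~``target_codes`` live nodes.

    Each epoch runs one depth-weighted batch update with the neighborhood
    radius shrinking linearly from ``radius_start`` (default: half the plane
    extent, i.e. ``initial_side``) to ``radius_end``, then splits the
    highest-priority nodes so that the node count grows linearly from
    ``initial_side**2`` to ``target_codes`` (final count lands in
    ``[target_codes, target_codes + 2]``).
    """
    g = initial_side
    if g < 1:
        raise ValidationError("initial_side must be >= 1")
    if target_codes < g * g:
        raise ValidationError(
            f"target_codes={target_codes} below the initial node count {g * g}"
        )
    if epochs < 1:
        raise ValidationError("epochs must be >= 1")
    X = _points(points)
    if X.shape[0] == 0:
        raise ValidationError("cannot train on an empty point cloud")
    if radius_start is None:
        radius_start = float(g)
    state = _init_state(X, target_codes, g, seed)
    radii = np.linspace(radius_start, radius_end, epochs)
    for e, r in enumerate(radii, start=1):
        _gqtsom_epoch(X, state, float(r))
        for addr in growth_step(state, epochs - e + 1):
            split_node(state, addr, float(r))
        state.epoch = e
    return state


def model_from_gqtsom(state: GqtsomState, meta: dict | None = None) -> LandmarkModel:
    """Landmark model from a trained GQTSOM: node weights as high-dimensional
    landmarks, quadtree-cell centers as low-dimensional ones; nodes ordered
    by ``(L, x, y)``; per-landmark depth recorded for plotting."""
    order = np.lexsort((state.ys, state.xs, state.levels))
    m = {
        "generator": "gqtsom",
        "initial_side": state.initial_side,
        "target_codes": state.target_codes,
        "levels": [int(v) for v in state.levels[order]],
    }
    if meta:
        m.update(meta)
    return LandmarkModel(
        high=state.weights[order].copy(),
        low=state.plane_coords[order],
        meta=m,
    )
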