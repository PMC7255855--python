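# Methods

## Model

The package embeds points of a high-dimensional cloud `X ∈ ℝ^{n×D}` into a
P-dimensional space (P = 2 by default, any P ≥ 2 supported) by
interpolation among paired landmarks `L ∈ ℝ^{n_L×D}` (input space) and
`l ∈ ℝ^{n_L×P}` (output space).  Each point is treated independently:

1. **Scoring.**  Landmark distances `c_i` are squared Euclidean norms (or
   L¹/L∞ values when the scoring metric is switched; the affine projections
   below always use dot products, which remain valid because
   minimal-distance projection onto a line is linear under those metrics
   too).  The `k` nearest landmarks (stable sort; ties to the lowest index)
   receive scores

       S_i = exp(b·(μ − c_i)/σ) · (1 − exp((c_i − c_k)/(m·c_k))) ,

   where `μ` is the 1/i-weighted mean of the k nearest distances and `σ`
   the matching weighted scale.  The harmonic weights emphasize near
   landmarks; any location/scale pair preserves the invariants that matter
   (S_k = 0 exactly, smoothness, scale-invariance at b = 0), so the choice
   is isolated in `neighbor_scores` and can be swapped.  If all k distances
   are equal (σ = 0) the first factor is taken as 1.

2. **Pair projections.**  For every unordered pair among the `k−1` closest
   landmarks, the scalar `d = ⟨X−L_i, L_j−L_i⟩/‖L_j−L_i‖²` locates the
   point's projection on the input-space line through the pair; the pair
   contributes the linear condition that the output project to the same
   `d` on the output-space line, with weight
   `s = (1+‖h‖²)^(−a) · exp(−(d−½)²) · S_i·S_j`, `h = l_j − l_i`.
   The Gaussian factor discounts pairs whose line the point does not sit
   between; the `(1+‖h‖²)^(−a)` factor discounts pairs of mutually distant
   output landmarks.

3. **Solve.**  The accumulated P×P normal system is solved by Cramer's rule
   for P ∈ {2, 3} and a batched LAPACK solve otherwise.  The solution
   minimizes `Σ s·‖h‖²·(d − ⟨x−l_i,h⟩/‖h‖²)²`; the test suite checks this
   equivalence against a derivative-free minimizer on random instances.

Smoothness in `X` follows from S_k = 0: a landmark entering or leaving the
active neighborhood always does so with zero weight (pairs use only the
`k−1` closest landmarks, and the (k−1)-th score vanishes exactly where the
ranking at the boundary changes).

### Parameters

| name | default | meaning |
|------|---------|---------|
| `k`  | `clamp(round(√n_L), 4, n_L)` | neighborhood size; the √ scaling keeps per-point cost `O(D·n_L)` |
| `m`  | 10      | decay steepness of scores approaching the k-th neighbor |
| `b`  | 1/e     | decay steepness for far landmarks, relative to the local distance scale |
| `a`  | 1       | penalty exponent on output-space pair length (units: none; 0 disables, making the map equivariant under uniform rescaling of `l`) |
| `metric` | euclidean | scoring distance only |

Degenerate cases: a point coinciding with ≥ k landmarks returns the output
coordinates of the first matching landmark; landmark pairs with (near-)zero
separation in either space are skipped (relative threshold `eps_h = 1e−12`
of the squared landmark spread); a singular accumulated system (relative
determinant below `eps_det = 1e−12`) raises an error advising a larger `k`
or `m`.  Singularity is not hypothetical: on grid-structured landmarks a
small `k` can select `k−1` landmarks lying on one lattice diagonal, whose
output-space directions are all parallel.  `k` at or above roughly twice
the grid side avoids this; the default √-scaling is adequate for irregular
(random or quadtree) landmark layouts but deliberately conservative, and
grid users should raise `k`.

Determinism: points are processed in fixed 256-row blocks whose boundaries
do not depend on the thread count, so `embed` is bitwise reproducible for
any `threads` value.

## Batch SOM landmark generator

A `width × height` lattice of codebook vectors is trained by whole-dataset
epochs: every point is assigned to its best-matching unit and every node
moves to the Gaussian-kernel-weighted mean of all points, the kernel taken
over integer grid coordinates with radius shrinking linearly from
`max(width, height)/2` to 0.5 over 10 epochs (all parameters explicit).
At radius 0 an epoch is exactly one Lloyd (k-means) step; at infinite
radius all nodes coincide with the global mean; codebook vectors always
stay in the convex hull of the data.  Initialization samples data rows
without replacement (seeded).

## Growing quadtree SOM (GQTSOM)

Nodes are quadtree leaves addressed `(L, x, y)` with plane position
`((2x+1), (2y+1))·2^−L`; training starts from a level-0 `g × g` grid
(g = 3 by default).  Each epoch runs one batch update on the plane
coordinates, then splits the highest-priority nodes — priority
`last_move/(L+1)`, where `last_move` is the input-space distance the node
moved this epoch — into their four children
`(L+1, 2x, 2y), (L+1, 2x+1, 2y), (L+1, 2x+1, 2y+1), (L+1, 2x, 2y+1)`,
removing the parent (net +3 nodes per split; count = g² + 3·splits always).
Child weights are interpolated from the pre-split nodes with the current
training kernel.

Two design points were genuinely open and resolved as follows:

- **Depth penalty.**  A depth-L node's neighborhood kernel *volume* is
  scaled by `4^−L`, implemented as kernel width `σ ∝ r·2^−L` (pairwise
  variance `r²·2^−(L_u+L_v)`).  The alternative — scaling the node's kernel
  *mass* by `4^−L` at full width — leaves deep nodes over-smoothed by their
  wide neighborhoods: in direct comparisons the map then allocates no more
  nodes to a 1 % rare population than a fixed grid does, defeating the
  generator's purpose.  With width scaling, deep nodes interact only
  locally and specialize; the rare-population test (20 seeds, 20 000
  points, 1 % rare cluster at 10 sd, 144-node maps) shows a median
  rare-node fraction of ~0.05 versus ~0.02 for an equal-size fixed SOM.
  The trade-off: weaker long-range coupling of deep nodes occasionally
  leaves a planar fold uncorrected late in training, so global layouts can
  be slightly less regular than a fixed grid's (the fixed SOM remains the
  better choice for strongly planar data).
- **Growth schedule.**  The node count tracks the straight line from `g²`
  to `target_codes` across the epochs: each epoch splits
  `ceil((ideal_count − count)/3)` nodes, where `ideal_count` lies on that
  line, capped by `ceil(deficit/3)` and the live-node count.  Tracking the
  original line (rather than re-deriving a slope from the remaining
  deficit each epoch) keeps the count within one split of linear; the
  final epoch closes any remaining gap, so the final count lands in
  `[target_codes, target_codes+2]`.
- The `L^−1` growth penalty is implemented as `1/(L+1)` to stay finite at
  the root level (monotone-equivalent for L ≥ 1).

## Generalized landmarks

`random_landmarks` samples input rows uniformly without replacement;
`attach_low` pairs any high-dimensional landmark set with externally
computed output coordinates (t-SNE, UMAP, PCA, manual).  The package never
invokes an external DR method itself; the low coordinates arrive as an
array or CSV whose row order matches the high matrix.

## Synthetic data

Three seeded generators cover the structures the method targets: an
isotropic Gaussian mixture (well-separated populations), a dominant blob
with a small satellite at a chosen separation (rare populations; defaults
1 % at 5 sd), and a noisy 2-D plane isometrically embedded in `ℝ^D`
(manifold recovery; ground-truth coordinates returned for Procrustes
evaluation).  Labels and true coordinates are returned for evaluation only.
What these fixtures do **not** emulate: cytometry spillover/compensation,
acquisition artifacts, heavy-tailed marker noise, or debris/doublet events
— passing tests demonstrate algorithmic correctness on clean population
structure, not robustness to instrument effects.

## Numerical and test-design notes

- Euclidean scoring uses squared distances throughout; the score formula
  is invariant to that monotone choice up to the μ/σ normalization.
- The PCA-limit check (2×2 SOM, k = 4, a = b = 0, m = 10⁶) uses a Gaussian
  cloud with axis scales (3, 2, 0.5, 0.3, 0.2) under a random rotation.
  The top-2 anisotropy is kept moderate (1.5 : 1) deliberately: a 2×2 SOM
  trained on a very elongated cloud collapses into a cross/rhombus (a
  known small-SOM topology artifact), which degrades the correspondence
  for reasons unrelated to the projection.  With ideally placed square
  landmarks the projection matches PCA to Procrustes correlation 0.99.
- Problem sizes in the test suite (clouds of 10³–2·10⁴ points, maps of
  30–150 nodes, 100 brute-force oracle instances) were chosen so the whole
  suite completes in well under a minute while every property remains
  comfortably resolved at its tolerance.
- File formats: model files are JSON (Python's shortest-round-trip float
  encoding makes save/load bit-exact); coordinate CSVs are written with
  `repr` precision and read back with round-trip float parsing; FCS
  support is a minimal read-only parser for FCS 3.0/3.1 list-mode files
  with uniform float/integer data (no delimiter escaping, no compensation
  or gating — preprocessing beyond the asinh transform is out of scope).

## Known limitations

- Landmark quality bounds embedding quality: the projection faithfully
  enriches whatever layout the landmarks provide, including its folds.
- Small `k` on lattice landmarks can yield singular systems (raised with a
  diagnostic, see above).
- The GQTSOM depth penalty trades global stiffness for local resolution;
  see the depth-penalty note.
- The FCS reader targets the common single-dataset list-mode case only.
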