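# embedsom

Fast landmark-directed embedding of high-dimensional single-cell data,
with two self-organizing-map landmark generators: a classic batch-trained
rectangular SOM and an inwards-growing quadtree-structured SOM (GQTSOM)
whose resolution adapts to small cell populations.

## The problem

Flow and mass cytometry experiments routinely produce millions of cells
with tens of marker intensities each.  Nonlinear embedding methods such as
t-SNE or UMAP give informative 2-D views but scale poorly, because they
optimize over relations between all pairs of points.  This package takes
the opposite route: first summarize the data by a few hundred *landmarks* —
paired positions `L ∈ ℝ^{n_L×D}` in marker space and `l ∈ ℝ^{n_L×P}` in the
output plane — then embed every cell independently, in time linear in the
number of cells and trivially parallel.

## The algorithm

For a point `X`, the projection

1. finds the `k` nearest landmarks and scores them,

   `S_i = exp(b·(μ−c_i)/σ) · (1 − exp((c_i − c_k)/(m·c_k)))`,

   where `c_i` are the (squared Euclidean, or L¹/L∞) landmark distances in
   ascending order and `μ, σ` summarize their local distribution.  The
   score of the k-th neighbor is exactly zero, which makes the map smooth
   in `X` even where the nearest-neighbor set changes;
2. for each pair `{i, j}` of the `k−1` closest landmarks computes the
   affine coordinate `d = ⟨X−L_i, L_j−L_i⟩ / ‖L_j−L_i‖²` of the point's
   projection onto the line through the pair;
3. asks that the output project to the same coordinate on the corresponding
   low-space line through `l_i, l_j`, weighting each pair by
   `s = (1+‖h‖²)^{−a} · exp(−(d−½)²) · S_i · S_j` with `h = l_j − l_i`;
4. solves the resulting P×P least-squares system (Cramer's rule for
   P ∈ {2, 3}).

Equivalently, the output minimizes `Σ s·‖h‖²·(d − ⟨x−l_i, h⟩/‖h‖²)²`.
The map is locally linear — with SOM landmarks it behaves like many local
PCA projections stitched smoothly together, and in the extreme setting
(2×2 SOM, `k = 4`, `a = b = 0`, `m → ∞`) it reproduces PCA almost exactly.

Landmarks can come from:

- `train_som` — batch SOM on a fixed `width × height` grid; grid positions
  are the low-dimensional landmarks;
- `train_gqtsom` — the growing quadtree SOM: nodes addressed `(L, x, y)`
  sit at `((2x+1), (2y+1))·2^−L` in the plane and split into four children
  where training movement is largest, so rare populations receive extra
  landmarks;
- `attach_low` — any external layout (t-SNE, UMAP, PCA, hand placement) of
  e.g. a random sample of points (`random_landmarks`).

## Worked example

```python
import numpy as np
from embedsom import (gaussian_mixture, train_gqtsom, model_from_gqtsom,
                      default_params, embed)

cloud, labels = gaussian_mixture(
    20000, centers=np.random.default_rng(0).uniform(-5, 5, (4, 8)), seed=1)

state = train_gqtsom(cloud, target_codes=100, epochs=15, seed=2)
model = model_from_gqtsom(state)
print(state.splits, model.n_landmarks)   # 31 102

coords = embed(cloud, model, threads=4)  # 20000 x 2
print(coords.shape, np.round(coords[0], 3))
```

prints

```
31 102
(20000, 2) [4.233 0.902]
```

— the map grew from the initial 3×3 grid by 31 splits to 102 landmarks
(each split replaces one node by four), and every cell received 2-D
coordinates inside the landmark plane `(0, 6)²`.  Cells of one mixture
component land in one compact region; `coords` can be plotted directly.

The same workflow from the shell:

```sh
embedsom synth --n 20000 --dim 8 --out data.csv
embedsom gqtsom --data data.csv --target-codes 100 --out model.json
embedsom embed --data data.csv --model model.json --out coords.csv
```

`embed` also reads FCS 3.0/3.1 cytometry files directly
(`--data file.fcs --channels CD3 --asinh 5`).

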