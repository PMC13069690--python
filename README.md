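# nichegrad

Boundary-aware spatial neighborhood analysis and spatially informed
differential expression for high-resolution spatial transcriptomics
(Xenium, MERFISH, Visium HD, and any platform that can export per-cell
coordinates plus a normalized expression matrix).

Most spatial DE tools look for globally spatially variable genes. nichegrad
instead models *local* tissue context: where a cell population ends (its
boundary), who its immediate neighbors are (rings and interaction matrices),
and how expression changes with proximity to a boundary or centroid
(distance-decay weights, spline gradients, enrichment scores).

## What it computes

**Boundaries.** For a cluster, cells with a large mean distance to their k
nearest neighbors (d̄_c > τ, default k = 5) are removed as spatial outliers;
the survivors are split into contiguous subregions (DBSCAN or k-means) and
each subregion is wrapped in a concave-hull polygon. Buffering a boundary
outward by a distance (default 100 units) yields a **ring region** — the
annulus holding the population's immediate neighbors.

**Spatial weights.** Each cell's distance d_c to a reference (the population
centroid s₀ = N⁻¹ Σ s_c, or the nearest point of a boundary curve) is
min-max normalized to d̃_c ∈ [0, 1] and passed through a decay kernel:

| kernel    | w_c               | range    |
|-----------|-------------------|----------|
| inverse   | 1 / (1 + d̃_c)     | [0.5, 1] |
| gaussian  | exp(−d̃_c²/2σ²)    | (0, 1]   |
| linear    | 1 − d̃_c           | [0, 1]   |
| quadratic | (1 − d̃_c)²        | [0, 1]   |

A weight of 1 marks a cell at the reference (exactly on the boundary, or at
the centroid).

**Neighborhood interactions.** M_ij counts how often cells of cluster i have
cluster-j cells among their k (default 10) nearest spatial neighbors, with
row-proportion or row-z scaling for display.

**Differential expression.** Group contrasts (inside vs ring, one-vs-rest
markers) use per-gene OLS with empirical-Bayes variance moderation: s̃_g² =
(d₀s₀² + d·s_g²)/(d₀ + d), with the prior (d₀, s₀²) estimated by
moment-matching on log s_g². Gradient DE models expression as a smooth
function of a spatial covariate t through an orthonormalized natural-cubic-
spline design Z (df = 3 by default) built from [1, t, ns(t)], testing all
spline coefficients with a moderated F; the sign of the first coefficient
("Z1", aligned to correlate positively with t) gives the trend direction.
P-values are Benjamini–Hochberg adjusted.

**Spatial enrichment index.** SEI_g = Σ w_c y_gc / Σ w_c, normalized by the
unweighted mean μ_g (plus ε = 10⁻⁶): uniform weights give exactly 1, values
above 1 flag genes concentrated where weights are high.

## Worked example

No data download is needed: the built-in generator plants clusters,
boundary gradients and null genes with known ground truth.

```python
import nichegrad as ng

cells, expr, truth = ng.generate_tissue(ng.fixture_config("small"))

bset = ng.get_boundary(cells, "A", tau=200, eps=120)      # 1 region
ring = ng.build_ring_region(bset.primary, dist=100)
ng.stats_cells_inside(ng.cells_inside(cells, ring))
#  cluster  count  proportion
#        B     91         1.0        <- the ring holds only annulus cells

w = ng.compute_boundary_weights(cells, bset.primary, decay="inverse")
ng.run_spatial_de(expr, w).head(3)[["gene", "effect", "adj_p", "trend_sign"]]
#         gene    effect        adj_p  trend_sign
#   marker_A_1 10.851463 6.586566e-20           1
#    grad_up_3 -9.621898 6.586566e-20          -1
# grad_down_12  8.673580 2.362719e-17           1

ng.compute_sei(expr, w).head(3)[["gene", "sei", "mu", "norm_sei"]]
#        gene      sei       mu  norm_sei
#  marker_A_1 1.503475 1.391132  1.080756
#  marker_A_7 1.382621 1.286683  1.074562
# marker_A_11 1.444910 1.351401  1.069194
```

Reading the output: inner-disc marker genes rise toward the disc boundary
from outside (positive trend, norm_sei > 1); planted "up" gradient genes
increase with distance from the boundary, so against boundary-proximity
weights they show negative trends — both directions are recovered with tiny
adjusted p-values while null genes stay at norm_sei ≈ 1.

The same pipeline is scriptable from a shell (`nichegrad simulate | boundary
| ring | inside | stats | interact | weights | de-group | de-markers |
de-spatial | sei | bin`), with TSV/GeoJSON/MTX files between stages and a
parameter manifest written next to every output.

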