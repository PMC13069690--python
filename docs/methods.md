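# Methods

This note documents the models implemented in nichegrad, the parameters
that matter, the numerical choices made where the design was open, and what
the synthetic-data tests do and do not demonstrate.

## Boundary detection

For a selected cell population, each cell's mean Euclidean distance to its
`k_outlier` nearest neighbors (default 5, self excluded) is compared to a
user threshold τ (platform units); cells above τ are spatial outliers and
dropped. Outlier removal runs once per cluster, *before* subregion
detection, so a threshold expresses an absolute density floor rather than a
per-subregion one. Survivors are split into contiguous subregions with
DBSCAN (`eps` in platform units, `min_pts` = 5, noise labeled −1 and
excluded) or k-means (explicitly seeded, default 0, for reproducibility).
`min_pts` = 5 mirrors the outlier-removal k; both should grow with cell
density.

Each subregion is wrapped in a concave hull. The hull is computed by GEOS
(shapely's `concave_hull`), which takes a ratio in [0, 1]; the package
exposes a `concavity` knob in [0, ∞) mapped as ratio = concavity/(1 +
concavity), so concavity → ∞ is exactly the convex hull and smaller values
hug the points more tightly (default 2.0, a mildly smoothed outline). An
optional `length_threshold` smooths away boundary detail below a given
segment length via Douglas–Peucker simplification; the simplified polygon
is unioned with the raw hull so the containment guarantee (every input
point inside or on the polygon) survives. Polygons are oriented
counterclockwise and regions numbered 1..R by descending area (region 1 =
"primary").

Ring regions buffer a boundary outward by `dist` (default 100 units) with
round joins — a true Minkowski offset; mitered joins would overshoot at
sharp vertices. Point-in-region tests are boundary-inclusive on both
curves, and ring membership is "inside outer AND NOT inside inner", so the
inner region and ring exactly partition the outer region. Cells exactly on
a detected boundary therefore never vanish from both sides.

Perimeter splitting snaps each anchor to its nearest polygon vertex
(distinct vertices required), cuts the ring at the snapped vertices, and
numbers edges counterclockwise from the vertex nearest the first anchor;
edge lengths always sum to the polygon perimeter.

## Spatial weights

Distances are measured either to the arithmetic centroid of a reference
population or to the nearest point of a boundary curve (the continuous
outline, not just its vertices — cells *inside* a polygon still get their
positive distance to the outline, because the weights index proximity to
the interface itself). Min-max normalization maps the selection's distances
onto [0, 1]; when all distances are equal the normalized distance is
defined as 0 (weight 1 everywhere), because single-ring or perfectly
symmetric selections legitimately occur and should not error.
Normalization is computed over exactly the cell selection passed in;
callers choose whether that scope is one subregion or several.

The four kernels (inverse, Gaussian, linear, quadratic) are applied
element-wise exactly as tabulated in the README. The Gaussian scale σ
defaults to 0.3, which puts the half-weight point near d̃ ≈ 0.35 and gives
visible decay across the unit range; it is the one weight parameter without
a canonical value and should be tuned to the gradient's expected reach.

## Interaction matrices

M_ij sums, over all cells c of cluster i, the number of cluster-j cells
among c's k nearest neighbors (default k = 10, Euclidean, self excluded —
including self would add exactly |C_i| to the diagonal and carries no
information). Row i therefore always sums to k·|C_i|, a conservation law
asserted in the tests against a brute-force pairwise sort. Neighbors are
found over exactly the table passed in; restricting an analysis to
ring-localized cells is done by passing that subset.

## Differential expression

### Fitting and moderation

Every gene is fit by OLS on a shared design with an explicit intercept.
For gradient DE the model written as Y_g = Zβ_g + ε_g is fitted as
Y_g = α + Zβ_g + ε_g: Z's columns are constructed orthogonal to the
constant vector, so α absorbs the gene mean without affecting β, while the
explicit intercept keeps the fit unbiased for uncentered expression.

Per-gene residual variances s_g² (shared residual df d = n − rank) are
moderated with the standard empirical-Bayes recipe: writing z_g = log s_g²,
the mean and variance of z are matched to their digamma/trigamma
expressions under a scaled inverse-χ² prior; the excess of var(z) over
trigamma(d/2) determines the prior df d₀ by trigamma inversion
(one-dimensional root finding bracketed on d₀/2 ∈ [10⁻², 10⁴]), and the
prior variance s₀² follows from the mean equation. No excess dispersion
(common on small or homogeneous panels) gives d₀ = ∞ and complete pooling
at the mean sample variance. Posterior variances s̃_g² = (d₀s₀² + d·s_g²)/
(d₀ + d) feed moderated t (group DE, df d₀ + d) and moderated F (gradient
DE, df (k, d₀ + d); the infinite-denominator case falls back to the χ²
limit). Setting the prior df to 0 disables moderation and exactly recovers
the classical pooled-variance statistics, which the tests use as an
independent oracle. BH adjustment is applied across the genes tested in one
call; no cross-call pooling.

### Group and marker modes

The two-group design is [1, indicator(a)], so the group coefficient is the
a-minus-b mean difference on the (already log-scale) expression and is
reported directly as the log fold change — its base is whatever the
upstream normalization used; no re-exponentiation is attempted. A `min_pct`
option (default 0) drops genes whose detection fraction (share of cells
with expression > 0) is below the cutoff in both groups; dropped genes are
returned flagged, not silently removed. Marker mode runs one-vs-rest per
cluster.

### Gradient (spatial) mode

The covariate t is a distance or weight vector. A natural cubic spline
basis with k degrees of freedom (default 3) is built by the truncated-power
construction: k − 1 interior knots at equally spaced quantiles of t,
boundary knots at min/max, curvature vanishing at the boundaries. Only the
basis's span matters, because the augmented block [t, ns(t)] is centered
and orthonormalized.

The orthonormalization is a fixed-order two-pass modified Gram–Schmidt over
the centered columns, dropping directions whose residual norm falls below
10⁻¹⁰ of the largest column norm (t lies in the span of {1, ns(t)} for a
natural spline, so the block is rank-deficient by construction and exactly
k directions survive). Processing t first pins Z's first column to the
centered, normalized covariate itself, which has two consequences the
package treats as requirements: corr(Z₁, t) = 1 > 0 without any sign
gymnastics (a sign flip is still applied defensively), and the whole design
— not just the test statistics — is exactly invariant to positive affine
rescalings of t, since quantile knots, centering and normalization all
commute with them. A pivoted QR would reach the same span but could reorder
columns under rescaling, destabilizing the reported Z1 coefficient.

The moderated F is taken jointly over all k spline coefficients
("testing across all coefficients"); per-coefficient moderated t values are
exposed as auxiliary columns. The reported effect is β_{g,1} (the Z1
coefficient) and the trend sign is its sign: positive = increasing with t.

## Spatial enrichment index

SEI_g = Σ_c w_c y_gc / Σ_c w_c with μ_g the unweighted mean and
norm_SEI_g = SEI_g/(μ_g + ε), ε = 10⁻⁶. SEI is a convex combination of the
gene's values; uniform weights give norm_SEI = 1 exactly (up to ε), and the
index is invariant to rescaling a gene's expression. It is computed over
the cells supplied — population selection is the caller's job — and is a
ranking score, not a test: no p-values are attached. Spearman correlations
between expression and weights optionally drop zero-expression cells first
(the default, matching how sparse panels are usually displayed); constant
input yields a flagged insufficient-variation result rather than an
exception. Binned summaries use equal-width right-closed bins over the
weight range, with empty bins reported as missing rather than zero.

## Synthetic tissues

The generator emulates the *structures* the methods target, not the
sequencing process: coordinates are drawn per layout (two separated blobs;
a disc nested in an annulus; two half-planes; three 1-D zones mimicking
zonation), and log-scale expression is Gaussian noise around planted means —
baseline 1.0, marker genes +2.0 inside their cluster, gradient genes a ±2.0
ramp over the normalized distance covariate, noise sd 0.5, 20% dropout
(zero-inflation) followed by clamping at zero. These defaults give a
slope-to-noise ratio of 4, a strong but not trivial signal. Named fixtures
(small: 400 cells × 60 genes, seed 11; medium: 5 000 × 300, seed 12) pin
the configurations used throughout the tests.

Because noise is Gaussian on the log scale, passing tests demonstrate
correctness of the geometry, weighting and linear-model machinery under the
model's own assumptions; they do not probe count overdispersion, segmentation
errors, or spatially correlated noise present in real platforms. The
acceptance checks therefore emphasize analytic identities, conservation
laws, and oracle equivalences that hold regardless of those features, with
problem sizes (hundreds of cells, ≤ 1000 genes) chosen so the entire suite
runs in a couple of minutes on one core.

## Degenerate inputs and tie-breaking

Coincident points: kNN ties are broken by ascending cell index; a cell
coincident with others still excludes itself from its own neighbor set.
All-equal distances normalize to 0 (weight 1). Constant interaction rows
z-score to all zeros. Welch t-tests on compositions with zero variance on
both sides return p = 1 when the means agree (and 0 otherwise) instead of
NaN. Genes with zero residual variance are shrunk up toward the prior; if
every gene has zero variance, moderation is skipped and flagged. Degenerate
covariates (too few distinct values for the requested spline df) raise
immediately with the achieved count.
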