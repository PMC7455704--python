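# Methods

## Model

`divergescan` treats differential expression as a question about spatial
arrangement rather than between-group contrasts. Cells live in an input
space of at least two dimensions — principal components, a t-SNE/UMAP
embedding, or physical coordinates of spatial capture spots. For each gene,
the cells are split into the detecting class (T) and the non-detecting
class (F), and the local density of each class over a fixed set of grid
points is compared to the density of all cells (the reference *Q*). The
score is the sum of the two class-conditional Kullback–Leibler divergences
from *Q*; each class distribution is normalized to sum to 1 separately, so
the two terms are ordinary KL divergences and the score is non-negative and
invariant to complementing the detection vector. The natural logarithm is
used throughout; the base only rescales all scores, and the randomization
null absorbs any monotone rescaling, so p-values do not depend on it.

The method assumes that detection (a hard binary threshold) captures the
biologically relevant variation. Two genes detected in the same cells
receive the same score even if their expression levels differ ten-fold;
continuous-expression variants are out of scope.

## Detection

* `median` (default): per-gene cutoff at the median of that gene's values
  across cells. For sparse count data whose per-gene median is 0 this
  reduces to "counts > 0".
* `threshold`: one global cutoff, default 1.0 — the usual choice for
  spot-level spatial data.

Comparisons are strict (`value > cutoff`): with `>=`, the median rule would
mark at least half of all cells as detecting every gene, including all-zero
genes. Genes detected in fewer than `min_detected` cells (default 10,
mirroring the common spatial prefilter "fewer than 10 spots above 1 count")
are removed as unstable under the null; genes detected in *every* cell are
removed because their class-T profile equals *Q* by construction and the
score is identically ~0.

## Grid, kernel and profiles

* 2D spaces: a k x k lattice with k = ceil(sqrt(n_grid)) levels spanning
  [min, max] of each axis. All lattice points are kept, including ones in
  empty regions (their mass is absorbed by the pseudocount). Default
  request: 100 points.
* Higher dimensions: exactly `n_grid` seeded k-means centroids of the cell
  coordinates (one initialization, 50-iteration cap, bit-reproducible for a
  fixed seed). Centroids track the occupied subspace and avoid the empty
  corners of a high-dimensional bounding box.
* Bandwidth *h*: median over cells of the Euclidean distance to the nearest
  grid point. Scale-adaptive (doubling coordinates doubles *h*); if every
  cell sits on a grid point, the mean nearest-neighbor distance among grid
  points is used. Overridable for sensitivity analyses.
* Kernel: untruncated Gaussian, weight(c, x) = exp(−d(c,x)² / 2h²). With at
  most a few hundred grid points the full cell x grid product is cheap, so
  truncation would be an optimization without semantic content.
* Profiles: raw kernel mass per grid point is normalized to 1, a fixed
  total pseudocount of 1e−9 (spread uniformly over grid points) is added,
  and the profile renormalized. The pseudocount keeps *Q* strictly positive
  (log *P*/*Q* is always defined) while being numerically negligible
  elsewhere; adding it after the first normalization makes profiles
  invariant to rescaling of weights.
* Coordinate scaling (`scale_coords`, default on): each input dimension is
  standardized to unit variance before any distance computation, preventing
  PC1 from dominating an isotropic kernel. Recommended off for physical
  spatial coordinates, whose axes share units.

## Randomization null and p-values

The null distribution of log D_KL depends almost entirely on the number of
cells detecting the gene, so randomization is performed at ~20
approximately log-spaced detection-count levels covering the observed range
(endpoints included), with 100 random detection vectors per level, instead
of shuffling each gene individually; this makes the cost O(levels) rather
than O(genes). Draws are without replacement; in the advanced mode they are
weighted by per-cell detected-gene totals via Gumbel-perturbed log-weight
top-k selection, which is equivalent to sequentially drawing cells with
probability proportional to the remaining weights.

Per-level means of log D_KL and log standard deviations are smoothed
against log count by least-squares cubic B-splines with df = 6 (df counts
basis columns beyond the intercept, so the fit has df + 1 parameters,
capped at the number of levels; a saturated fit interpolates). Fitting the
standard deviation on the log scale keeps the curve positive. Outside the
fitted count range both curves are clamped to their endpoint values —
polynomial spline tails diverge. Fewer than 4 distinct levels fall back to
a constant model; a degenerate zero spread at a level is floored at 1e−6
with a warning.

A gene's z-score is (ln D_KL − mean_curve(ln n)) / sd_curve(ln n); the
one-sided upper-tail normal log-survival function gives log10 p directly in
log space, so genes hundreds of orders of magnitude beyond the null do not
underflow. Only excess divergence is tested — a deficit has no
interpretation here. Benjamini–Hochberg adjustment is computed in log10
space (step-up with cumulative minima) and reported, but ranking — raw p
ascending, ties broken by descending D_KL — is the primary output: because
the embedding itself is built from the expression data, absolute p-values
are inflated in real datasets.

## Advanced mode

Per-cell weights proportional to each cell's total number of detected genes
(cells with zero detected genes receive the minimum positive total) enter
the reference distribution *Q* and the randomization sampler. The observed
class profiles are left unweighted. A gene whose detection simply follows
per-cell depth then resembles both the weighted reference and the weighted
null draws, losing significance, while a gene running against the depth
gradient diverges more strongly from both.

## Synthetic benchmark

The generator emulates cluster-structured droplet scRNA-seq data:

* gene baseline means log-normal(−1, 1) — median ~0.37 counts per cell, a
  typical depth for droplet data at a few thousand total counts per cell;
* each gene x cluster pair receives a multiplicative DE factor with
  probability `de_prob` (default 0.1); factors are exp(±de_strength·|N(0,1)|)
  with random sign, so `de_strength` = 0 disables all effects;
* per-cell library-size factors log-normal(0, 0.25);
* counts negative binomial with dispersion 0.5 (variance μ + 0.5 μ²);
* path mode wires each cluster to a uniformly chosen earlier cluster and
  places each cell at a uniform pseudotime along the incoming edge,
  interpolating mean vectors linearly — gradual structure instead of
  discrete blocks.

Ground truth follows the established benchmark convention: a gene's DE
score is Σ over clusters of |log2 factor|, and the `n_deg` (default 100)
genes with the highest score — the strongest effects in the DE pool — are
the true DEGs, ties broken by gene index. Rankings are scored by ROC AUC in
the Mann–Whitney form (ties at half weight); genes dropped by detection
filtering are assigned a shared worst rank so that discarding true DEGs is
penalized rather than excused.

The companion embedding is a plain PCA of log1p counts (randomized SVD,
deterministic seed, component signs fixed by the largest-magnitude
loading), standing in for a full toolkit's preprocessing. What these
simulations do *not* emulate: dropout structure beyond NB sampling,
batch effects, mixed cell-type hierarchies, or the empirical mean-variance
trends of any specific platform — passing benchmarks here demonstrates the
machinery and its calibration, not performance on any particular tissue.

A second generator builds a 2D sheet whose per-cell detected-gene totals
form a linear spatial gradient, with two probe genes detected in cells
sampled proportionally to (gene `track`) or against (gene `anti`) the
gradient — the construction used to demonstrate the advanced mode.

## Problem sizes and numerical choices

Shipped tests and the reproduction script use 1000-cell / 5000-gene cluster
benchmarks (3 seeds), a 2000-cell / 500-gene uniform null for calibration,
and small closed-form instances for exactness; these sizes give stable
statistics while keeping a full run in the tens of seconds on one CPU. The
pipeline itself scales to tens of thousands of cells: the dominant costs
are one n_cells x n_grid kernel matrix and one n_genes x n_grid product.

Ties in ranking are broken by descending D_KL and then by table order
(stable sort). All randomness flows through explicit integer seeds: grid
placement, randomization draws, simulation, and embedding are
bit-reproducible, and repeated runs write byte-identical result files.

## Known limitations

* Hard detection thresholds discard magnitude information.
* P-values inherit the double use of expression data (embedding + test) and
  should be read as ranks in real data.
* Genes detected in very few cells are filtered rather than scored; real
  rare-population markers below `min_detected` cells are invisible.
* The high-dimensional grid construction and the bandwidth rule are
  package-specific choices; results are empirically stable to moderate
  changes in both (Spearman > 0.8 across half/double settings on the
  shipped benchmarks), but other constructions are possible.
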