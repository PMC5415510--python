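# Methods

## Model and assumptions

The package partitions n spatial units (watershed polygons, lattice cells,
any planar units with a contiguity relation) into k regions that are both
homogeneous in a feature space and spatially contiguous. It assumes:

* an undirected contiguity graph covering the units (rook adjacency by
  default when derived from polygons: a shared border of positive length);
* numeric features that are meaningful after standardization (each variable
  is reduced to mean 0, variance 1 before any distance is computed);
* a **connected** graph. Spatially isolated units (islands) make the
  constrained affinity graph disconnected and the spectral step refuses
  them; remove them (`PreprocessConfig.drop_units`) or bridge them first.

### The constrained affinity

Feature similarity is a Gaussian radial basis kernel on Euclidean distance
in the reduced feature space, `W_ij = exp(−d_ij²/2σ²)`. The spatial
constraint matrix is binary: `Q_ij = 1` iff the breadth-first hop distance
between i and j is at most δ. The clustering affinity is the Hadamard
product `S = W ∘ Q`.

We read the constraint as a *mask*: pairs farther apart than δ hops have
their affinity removed entirely, pairs within δ hops keep their feature
similarity. Small δ therefore forces the spectral geometry to be dominated
by near-neighbor structure — regions come out almost perfectly contiguous —
while large δ lets feature similarity act over long ranges and contiguity
degrades toward unconstrained clustering. This reading matches the observed
direction of the contiguity metric (PctML highest at δ = 1, lowest at large
δ) in both our synthetic grids and the published applications of the
algorithm; the alternative literal reading ("pairs within δ are required to
be in the same region") would predict the opposite trend and is not
implemented.

### Bandwidth σ

Default: the median embedding-space distance over adjacent (δ = 1) unit
pairs, falling back to the median over all pairs when no adjacent pair has
positive distance. This is scale-adaptive (rescaling all features rescales
σ proportionally, leaving W unchanged) and resolution-independent. It is
always recorded in the run's provenance and can be overridden
(`ClusterConfig.bandwidth`).

### Spectral step

`spectral_embed` solves the generalized eigenproblem `L u = λ D u` with
`L = D − S` and `D = diag(rowsum(S))` — random-walk normalized spectral
clustering — and returns the eigenvectors of the k smallest eigenvalues in
ascending order. No additional row normalization of the embedding is
applied by default; the Ng–Jordan–Weiss variant (rows projected to the unit
sphere) is available behind `row_normalize=True`. Up to n = 2,000 a dense
LAPACK generalized solver is used; above that, sparse shift-invert Lanczos
(`eigsh` with a small negative shift, since λ = 0 is always in the
spectrum). Sign indeterminacy is fixed deterministically: each eigenvector
is flipped so its largest-magnitude entry is positive.

### k-means step

Each of `restarts` (default 1,000; desk-scale examples and tests use
10–50) runs seeded k-means++ once from an independent seed-sequence
stream; the winner has the lowest within-cluster sum of squares. By
default the objective is measured in the space being clustered (the
spectral coordinates); `restart_selection_space="features"` instead scores
each restart's labels in the original feature space. The best-so-far
objective is non-increasing in the number of restarts under a fixed seed,
and the whole pipeline is byte-reproducible from (inputs, config, seed).

### Baselines

* `SC` — contiguity-only spectral clustering: the same pipeline on Q alone
  (equivalent to SSC with constant features, since a constant W makes
  W ∘ Q ∝ Q).
* `KMEANS` — restarted k-means directly on the reduced features; ignores
  the graph entirely.
* `RANDOM` — uniform labels resampled until no region is empty; the null
  model for region-number selection. It is *not* constrained to contiguous
  regions: it models "no consideration of homogeneity or contiguity".

## Preprocessing

Order of operations: impute → winsorize → standardize → PCA.

1. **Imputation.** A missing value is replaced by the mean of its unit's
   graph-neighbors' known values for that variable, iterated (default 10
   rounds) so values imputed in one round can feed the next; cells still
   missing (isolated units, fully missing neighborhoods) fall back to the
   column mean. This is the simplest interpolation that honors the spatial
   structure already required by the constraint machinery; no kriging.
2. **Winsorizing.** Values with |z| > 6 (configurable) are clamped to the
   ±6 SD bound rather than dropping their units: dropping units silently
   changes the contiguity graph, so unit removal is only ever explicit
   (`drop_units`). Clamping never moves a value across the column mean.
3. **Standardization.** Mean 0, variance 1 per variable; constant columns
   are dropped with a warning (erroring would make degenerate synthetic
   inputs unusable).
4. **PCA.** The minimal number m of leading components whose cumulative
   explained variance reaches `variance_threshold` (default 0.85) is
   retained. By default the retained scores are whitened to sample variance
   1 per axis ("unweighted" axes: each retained component contributes
   equally to the distances the RBF kernel sees); `whiten=False` keeps
   eigenvalue-scaled scores, which is equally defensible when the leading
   axes should dominate.

## Evaluation

* `SSW = Σ_regions Σ_{i∈region} ‖x_i − x̄_region‖²`,
  `SSB = Σ_regions n_region‖x̄_region − x̄‖²`; they sum to the total SS
  exactly, and `ratio = SSW/SSB` is reported as +inf when SSB = 0 (k = 1 is
  a legal query, not an error).
* Landscape reports default to the standardized clean-variable space; the
  PCA space is available (`ExperimentConfig.eval_space="pca"`). Response
  reports use the single response column.
* **PctML** is the percentage of unordered unit pairs within `eval_delta`
  hops assigned the same region. The constraint set defaults to the δ used
  for clustering; for methods without a δ (k-means, random) it defaults to
  1 (plain adjacency), the only δ-free choice.
* A region is *contiguous* when its induced adjacency subgraph is
  connected; the report counts such regions.

## Choosing the number of regions

E[SSW] for a uniform random partition is `TotalSS·(n−k)/(n−1)` — exactly
linear in k — so SSW always falls with k and an elbow alone is not evidence
of structure. The selection statistic is the **ratio of slopes**: the
per-unit-k finite difference of the constrained SSW curve divided by that
of the mean random SSW curve, each computed over a grid interval and
attributed to the interval midpoint (where a finite difference estimates a
derivative). While real regional structure is being discovered each added
region removes far more SSW than random relabeling and the ratio is large;
once structure is exhausted the constrained curve declines at a rate
comparable to the null and the ratio settles near 1.

A note on a tempting alternative: taking the ratio of slope *changes*
(second differences) is degenerate, because the null curve is linear in
expectation — its slope changes are pure Monte-Carlo noise, so the
statistic's denominator carries no signal. We verified this empirically:
with second differences the selected window lands at arbitrary points of
the post-elbow plateau.

Because the empirical ratio fluctuates around its plateau, it is averaged
over windows `[k − w/2, k + w/2]` centered on every grid point (default
w/2 = 10, i.e. window size 21 on a unit grid). The chosen k is the **first
local minimum** of |window average − 1| scanning k upward — the first
window at which the constrained curve has come closest to declining like
random. Windows whose average equals 1 exactly carry no information and
are excluded (they occur only in degenerate noise-free geometry); if the
distance decreases monotonically to the end of the grid, the last center
is returned. A relative tolerance (1e-9) keeps round-off on flat stretches
from registering as spurious upturns. If every window is excluded the
curves are indistinguishable from random and selection raises an error.

Within the k-sweep, SSC runs use reduced restarts by default
(`restarts_per_k=10`, configurable); full-fidelity sweeps should raise
this. The default grid is step 5 over 5–600, step 10 over 610–800, step 50
over 850–1000; grid points with k ≥ n are skipped with a warning.

## Region drivers and response variance

* **Variable importance.** A random forest (default 500 trees, Gini
  criterion, scikit-learn classification defaults otherwise, fully seeded)
  predicts region membership from the raw standardized variables.
  Importances are scikit-learn's normalized mean decrease in Gini impurity
  (they sum to 1 across variables); out-of-bag error accompanies them.
  Constant variables score exactly 0. k = 1 is an error (no target).
* **Response partitioning.** Points map to regions through their containing
  unit; points with missing responses or in units outside the
  regionalization are dropped with logged counts. The report's
  `among_fraction = SSB/(SSW+SSB)` is invariant to affine transformation of
  the response. Temporal aggregation (e.g. multi-year summer means per
  lake) is the caller's responsibility.

## Synthetic data generator

The generator emulates the *structure* the pipeline exercises, not the
distributions of any real dataset:

* a rook-adjacency lattice stands in for real polygon contiguity —
  planar, trivially verifiable adjacency;
* planted regions are contiguous by construction: seeded multi-source
  randomized BFS growth (irregular, watershed-like shapes) or rectangular
  blocks (deterministic geometry for exact tests);
* features come in three theme blocks (terrestrial/climate/freshwater); a
  random half of each block is informative. Region means are placed on a
  regular simplex scaled so every pair of regions is separated by
  `effect_size × noise_sd` in the informative subspace (falling back to
  scaled random directions when the informative dimension is below the
  region count); Gaussian noise is white by default, optionally spatially
  autocorrelated (Gaussian-filtered lattice noise, rescaled to `noise_sd`);
* missing cells and ±10 SD outliers are injected at stated rates;
* point responses are a per-region effect plus residual noise. The region
  effect variance σ_b² is solved from the balanced one-way ANOVA
  expectation `E[SSB]/E[SSB+SSW] = a` with
  `E[SSB] = (k−1)σ² + n(1−1/k)σ_b²` and `E[SSW] = (n−k)σ²`, so the
  *expected* SSB share equals the target `a` (e.g. 0.4); the realized share
  fluctuates with Monte-Carlo error, dominated for small k by the χ²
  spread of the k drawn effects.

What passing tests on this generator do **not** show: behavior under real
spatial covariance structures, non-Gaussian and skewed variables (e.g.
land-use proportions), real watershed geometry with highly variable
neighbor counts, or dataset-scale n. The full-scale pathway is documented
in `scripts/lagos_integration.py` and is deliberately outside the test
suite.

## Problem sizes and numerical choices

The validation suite runs on 20×20 to 25×25 lattices (400–625 units),
10–50 restarts, 40–200 random null replicates, and a k grid of 2–40 —
sizes at which exhaustive oracles (brute-force k-means minima over 4^11
assignments, 2^9 normalized-cut enumerations, dense eigendecompositions)
remain computable for cross-checking. Monte-Carlo assertions use 3
standard-error bands. Stated defaults (1,000 restarts, 200 random
clusterings, the 5–1,000 grid) are the full-fidelity settings.

Other numerics: hop reachability is computed by boolean sparse matrix
powers with early exit at transitive closure; dense similarity matrices
are refused above 30,000 units (`graphs.DENSE_LIMIT`); k-means labels are
canonicalized by first appearance before being mapped to 1..k; every
downstream metric is invariant to label permutation (tested).

## Known limitations

* The δ-hop constraint is purely topological; no geodesic or
  centroid-distance constraints, no soft (weighted) constraint matrices.
* No alternative constrained-clustering algorithms (SKATER, REDCAP, max-p)
  and no hierarchical output.
* Region-number selection inherits the noise of its two empirical curves;
  with weak regional signal the slope-ratio plateau can sit well above 1
  and the chosen window then reflects where improvement *slows* rather
  than vanishes. The full window-average series is always returned for
  inspection.
* The generator's among-region variance targeting is exact only in
  expectation and approximately balanced allocation.
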