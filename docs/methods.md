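# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `forestbeta`. Everything quantitative stated here is
computed by the test suite (`tests/`), the analysis drivers
(`analysis/`) or `scripts/acceptance.py`; nothing is asserted that the
code does not measure.

## 1. Beta-diversity metrics (`beta`)

Two inter-community distance classes are computed on a species distance
matrix δ:

* **D_pw** (basal): the mean over all directed species terms of the
  mean cross-community distance δ̄, normalized by n_{k1} + n_{k2}. The
  self term δ(i, i) = 0 is included in δ̄ when species i occurs in the
  target community — the convention of the standard community-
  phylogenetics implementations of these metrics, which keeps shared
  species pulling the statistic down.
* **D_nn** (terminal): the same construction with the nearest-neighbour
  distance min_{s∈k} δ(i, s).
* **D_pw′ / D_nn′**: species terms weighted by within-community
  relative abundance; the normalizer is 2 because each community's
  weights already sum to one. With equal abundances the primed forms
  reduce exactly to the unweighted ones.

Deliberate properties, asserted in tests: D_nn of identical communities
is 0 while D_pw of a community with itself equals its mean intra-
community pairwise distance; D_nn ≤ D_pw is *not* guaranteed; every
statistic scales linearly in δ. The vectorized all-pairs engine
(`pair_beta_matrices`) is checked against an independent brute-force
double-loop implementation to 1e−12 on random instances.

## 2. Null model and standardized effect sizes (`nullses`)

The null shuffles species names across the tips of the tree or
dendrogram — implemented as one joint row/column permutation of δ —
and leaves the community matrix untouched, so species occupancy,
abundance and spatial aggregation are all conditioned on.

S.E.S. = −(obs − null mean)/null sd, with the sample (n−1) sd over
`n_null` replicates (default 999; 199 in the scaled experiments).
Negative S.E.S. ⇔ turnover faster than expected. Pairs with zero null
sd (e.g. a two-species pool, where every shuffle is distance-
preserving) are flagged undefined and excluded downstream with a logged
count.

One permutation stream is reused across all subplot pairs within a run.
Per pair this is the same marginal null distribution as independent
per-pair shuffles; it only introduces dependence *between* pairs, which
none of the downstream summaries (per-pair S.E.S., group means) is
sensitive to, and it turns 999 × O(pairs) engine runs into 999 runs.

Calibration, measured at 199 nulls × 10 seeds on communities drawn at
random from a 20-species pool (16 subplots × richness 8 per replicate):
pooled S.E.S. mean within ±0.07, fraction beyond ±1.96 about 5%.
S.E.S. values of pairs from one replicate are strongly correlated
(shared pool, tree and nulls), so the pooled mean converges slowly in
the number of *replicates*, not pairs; the 16-subplot design keeps its
sampling noise well inside the calibration bounds.

## 3. Trait space (`traitspace`)

Traits are z-scored (units differ by orders of magnitude), reduced by
PCA to 3 axes, and the Euclidean distance on those scores is clustered
by classical unweighted UPGMA (cluster-to-cluster distance = unweighted
mean of member pairwise distances; merge height = d/2). Ties are broken
lexicographically by smallest member label, so identical inputs give
byte-identical newick output. The dendrogram's cophenetic distance
(2 × merge height of the smallest common cluster) is the functional δ.
UPGMA is validated against scipy's average-linkage cophenetic matrix on
random instances and against a hand-run 3-taxon example.

## 4. Soil geostatistics (`soilenv`)

* **Empirical variogram**: Matheron estimator on 15 lag bins up to one
  third of the maximum pairwise distance (longer lags carry few,
  strongly dependent pairs and destabilize fitting).
* **Model fit**: weighted least squares (weights = pair counts) of an
  exponential (default) or spherical model. "Range" is the e-folding
  correlation length L in γ(h) = nugget + psill·(1 − exp(−h/L)) — the
  same convention the landscape generator uses, so recovery tests
  compare like with like. Parameters are bounded (psill by 5× the
  largest binned semivariance, range by 2× the largest lag) to exclude
  the degenerate near-linear limit. On 500-point samples from an
  exponential field the median recovered range over seeds is within a
  factor two of truth; single realizations at small extent/range ratios
  can honestly look longer-range.
* **Block kriging**: ordinary kriging in semivariance form with a
  Lagrange multiplier; the block mean is approximated by a 4×4 point
  discretization per subplot (configurable). One factorization serves
  all blocks. Weights sum to 1 to 1e−8 by construction (asserted);
  zero-nugget prediction at a sample point is exact. Coincident sample
  points are deduplicated with a warning. The search neighbourhood is
  global — appropriate at these problem sizes.
* **Environmental distance**: soil variables z-scored (units differ
  wildly, so correlation-matrix PCA is the defensible choice), PCA,
  Euclidean distance on the first 3 component scores.

## 5. MRM and variation partitioning (`mrm`)

OLS on vectorized strictly-lower triangles. Inference permutes the
rows and columns of the *dependent* matrix jointly and refits
(Lichstein-style MRM): upper-tail p for R², two-sided on |coefficient|
for slopes, p = (1 + #{perm ≥ obs}) / (1 + n_perm). Perfectly
collinear explanatory matrices are rejected by name.

Partitioning fits three models (geo+env, geo, env):
pure_geo = R²_full − R²_env, pure_env = R²_full − R²_geo,
shared = R²_geo + R²_env − R²_full (may be negative; reported as-is).
Because published tables are not always explicit about which rendering
they print, the output table carries both the differenced pure
fractions and the marginal single-matrix R² values side by side.

## 6. Habitat classification and contrast (`habitat`)

Topographic metrics per subplot: mean elevation, mean gradient
magnitude (finite differences at field resolution), and convexity
(subplot mean elevation minus the mean of edge-adjacent subplot means;
border subplots use available neighbours). Two classifiers are
provided: k-means (k=3) on z-scored metrics with clusters named
valley/slope/ridge by ascending mean elevation (default), and an
elevation-tercile threshold rule. Exact habitat-delineation rules vary
between published plot studies; both options are declared
approximations.

The contrast partitions subplot pairs into within-habitat (V-V, S-S,
R-R) and across-habitat (V-S, V-R, S-R) groups and compares mean
S.E.S. by a pooled-variance Student's t test (Welch behind a flag).
Pairwise S.E.S. values are not independent observations; the test is
inherited from the study design and reported as a descriptive contrast,
not corrected for pair dependence.

## 7. Synthetic forest generator (`simulate`)

The generator emulates the data structure of a 20-ha tropical FDP
census (defaults: 400 × 500 m, 10⁵ stems, 450 species, 8 traits,
10 soil variables, elevation relief 708.2–869.1 m) and, for the test
experiments, a scaled 1-ha version (2,000 stems, 50 species) chosen so
the full pipeline runs in seconds per replicate.

* **Phylogeny**: pure-birth (Yule) tree, depth normalized to 1.
* **Traits**: each trait loads on a shared latent axis (loadings
  geomspace 0.85 → 0.3 across the 8 traits), with both the latent axis
  and each trait's own component drawn as w·(Brownian motion along the
  tree) + (1−w)·iid normal, standardized per trait; w defaults to 0.7.
  The latent axis mimics the dominant spectrum of covariation in real
  trait tables — it is what makes the first three trait PCs carry ~70%
  of the variance, as measured trait data do; fully independent traits
  would put only ~37% there and are not a realistic emulation.
* **Landscape**: Gaussian random fields with exponential covariance,
  simulated by circulant-embedding FFT (negative embedding eigenvalues
  clipped — the standard approximation). Soil variables share a latent
  fertility/moisture field (per-variable loadings 0.3–0.9), matching
  the strong cross-correlation of real FDP soil data; the filtered
  scenario couples that latent field to topography
  (`env_elevation_corr`, 0.95 in the scaled preset) so habitat types
  carry the environmental gradient. Elevation is min–max rescaled to
  the configured relief.
* **Census**: regional abundances are log-series; each species'
  environmental optimum μ_s maps its first trait linearly onto the
  observed range of a designated soil field (default `total_N`), so
  filtering induces functional and (through w) phylogenetic turnover.
  Stems follow a Thomas cluster process (parents uniform, Gaussian
  offspring displacement, sd 10 m scaled / 15 m full) thinned by
  exp(−(E(x)−μ_s)²/(2σ_f²)); `neutral` accepts everything, `filtered`
  uses σ_f = 0.25 (field sd ≈ 1), `mixed` σ_f = 1. Cluster parents
  establish under the same filter, so clusters sit inside suitable
  habitat. In the σ_f → 0 limit rejection sampling falls back to the
  most suitable candidate sites seen; an error is raised only when
  acceptance is numerically zero everywhere.
* **Soil sampling**: base points on a regular grid (30 m full-size,
  10 m on the scaled 1-ha plot — denser than pro-rata because kriging
  from ~13 points would dominate every downstream error budget), plus
  satellites per base at the paired radii (2 & 5, 2 & 15 or 5 & 15 m)
  along one random bearing. Published totals for this classic design
  are internally inconsistent, so satellites-per-base is configuration
  (default 2). Values are read at the nearest 5-m field node,
  optionally with observation noise.

### What the generator does and does not emulate

It reproduces the *statistical structure* the analysis assumes:
spatially aggregated conspecifics, log-series abundances, spatially
autocorrelated and cross-correlated soils, traits with tunable
phylogenetic signal, topography-linked environment. It does not model
demography through time, seed/seedling stages, interspecific
competition, or observation error in the census. Passing tests
therefore show the *pipeline* recovers known assembly processes from
data with this structure — not that any particular real forest is
assembled by them.

## 8. Scaled experiment design and measured operating characteristics

The replicated experiments (`experiments`) run at: 1 ha, 2,000 stems,
50 species, 20 m subplots for variation partitioning (25 cells), 10 m
subplots for the habitat contrast (100 cells — the proportionate
analogue of 20 m cells on 20 ha), 199 nulls, elevation-tercile
habitats, occurrence-based S.E.S. D_pw of the trait-dendrogram source
for the habitat contrast (the abundance-weighted forms inherit heavy
dominance noise from a 50-species log-series pool; the phylogenetic
source additionally depends on the per-realization phylogenetic signal
of the filtered trait, which a Yule+BM model leaves honestly variable).

Measured on seed blocks disjoint from any fixed test seeds (40
replicates each): the filtered scenario yields pure_env > pure_geo in
~93% of replicates, neutral yields pure_geo ≥ pure_env in ~98%, and
the within- > across-habitat S.E.S. direction holds with p < 0.05 in
~95%. These rates — not certainties — are what the ≥ 8/10 replicate
tests sample from.

## 9. Numerical and policy choices

* Coordinates live in half-open intervals [0, width) × [0, height);
  a stem on the max edge is invalid input. Grid cells are indexed
  row-major from the origin corner.
* Species missing from the tree or trait table are dropped from the
  corresponding analysis with a logged count (reconciliation report).
* Empty subplots are excluded from beta/SES tables and dropped listwise
  from all MRM matrices.
* All randomized operations take explicit seeds; rerunning a pipeline
  with the same config and seed is byte-identical (asserted).
* Full-size runs (20 ha, 10 m scale, 999 nulls) are supported by the
  same code paths but involve ~2×10⁶ subplot pairs per null replicate;
  the shipped presets use the scaled conditions above.

## 10. Known limitations

* The weighted-form normalizer (2) follows the standard definitions of
  these metrics; if a variant normalization is ever needed it is a
  one-line change in `beta`.
* MRM p-values treat pairwise distances as the unit of inference under
  matrix permutation; as in all Mantel-family methods, they are valid
  for the matrix-level null, not for pair-level independence.
* Kriging assumes isotropic, second-order stationary fields; no
  co-kriging or anisotropy.
* The habitat classifiers are generic stand-ins for plot-specific
  delineation rules.
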