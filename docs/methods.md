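# Methods

`rlqspace` analyses how environmental gradients filter the functional
traits and phylogenetic lineages of trees across spatial scales in a
mapped forest plot. This note documents the models and procedures the
package implements, the choices made where the design was open, and the
limits of what the synthetic test bed demonstrates.

## The five-matrix problem

The data are five matrices linked through a site-by-species abundance
table **L** (quadrats x species): an environment table **E** (quadrats x
soil/topography variables), a spatial basis **S** (quadrats x Moran's
eigenvector maps), a trait distance matrix **T** (species x species) and a
phylogenetic distance matrix **P** (species x species). Each matrix is
first ordinated on its own terms — **L** by correspondence analysis (CA),
**E** by row-weighted PCA, **S** by PCA of the MEM basis, **T** and **P**
by principal coordinate analysis (PCoA) — and the extended RLQ then seeks
the pair of axes (one through sites, one through species) maximizing the
covariance through **L** between the combined environment/space side and
the combined trait/phylogeny side.

### Correspondence-analysis weighting

With `P = L / L..`, row margins `r` and column margins `c`, the
CA-standardized table is `L0 = P / (r c^T) - 1`. `rlq_core(R, L, Q)`
computes the SVD of `R~^T D_r L0 D_c Q~`, where `R~` and `Q~` are the
site- and species-side tables centered (and, for raw variables, scaled)
under `D_r = diag(r)` and `D_c = diag(c)`. Eigenvalues are squared
singular values; total co-inertia is their sum, and it equals the sum of
squared fourth-corner statistics over all variable pairs — an identity the
test suite checks numerically.

### Block preparation for the extension

The site side concatenates the standardized environment block with the MEM
block; the species side concatenates trait-PCoA axes with phylogeny-PCoA
axes. Three choices matter here:

- **Equal block influence.** Each block is rescaled so its total weighted
  inertia is 1 before concatenation. Nothing in the problem says whether
  environment should outweigh space (or traits outweigh phylogeny), so
  equal a-priori inertia is the neutral default, and it is applied
  identically in the RLQ and in the global fourth-corner tests so their
  statistics are mutually consistent.
- **Axes keep their inertia.** Ordination axes (MEM, PCoA) are centered
  under the CA weights but *not* rescaled per-axis: an axis carrying 40%
  of trait variance should influence the co-inertia more than one carrying
  1%. Equalizing axis variances was tried during development and
  demonstrably destroys the power of the species-side permutation test —
  dozens of noise axes drown the leading structure.
- **Weight reconciliation.** MEM vectors and PCoA axes are built under
  uniform site/species weights but consumed under CA weights; they are
  re-centered (not re-orthogonalized) under the CA weights at use time.
- **PCoA axis count.** The smallest number of axes reaching 95% of the
  positive (corrected) inertia is retained.

Axis signs follow one convention everywhere: the largest-|loading| entry
of each axis is positive, which makes seeded runs byte-reproducible.

## Fourth-corner tests

The fourth-corner statistic for a quantitative site variable and a
quantitative species variable is the Pearson correlation on the
individual-level inflated table, computed as the CA-weighted cross product
of the standardized variables (verified against literal table inflation to
1e-12). Significance uses two permutation null models: model 2 permutes
the rows of **L** (breaks the site-environment link, preserves all
species-side structure) and model 4 permutes its columns (breaks the
species-trait link). The combined p-value is the maximum of the two — the
conservative sequential rule: an association is only called when it
survives breaking *either* link. For the combined test the standardized
effect size (SES) is computed against the pooled model-2 + model-4 null
draws. Global matrix-pair tests (E-T, E-P, S-T, S-P, and the full
R-Q) use the total co-inertia of the prepared blocks as the statistic,
with upper-tail p-values (co-inertia is non-negative). Per-pair tables
report raw p-values alongside a Holm adjustment across the variable grid;
both conventions are emitted because neither is canonical.

Permutation p-values use the add-one rule `(count + 1) / (n_perm + 1)` and
can therefore never be 0. Default `n_perm = 999`.

## Dispersion: NRI and S.E.S. PW

Per quadrat, the observed statistic is the abundance-weighted mean
pairwise distance among individuals,

    MPD = sum_{i != j} f_i f_j d_ij / sum_{i != j} f_i f_j,

with `f` the within-quadrat relative abundances and conspecific pairs
excluded. `d` is the patristic distance on the phylogeny (for NRI) or the
cophenetic distance on the UPGMA dendrogram of the Gower trait distances
(for S.E.S. PW) — the dendrogram rather than raw Gower because the trait
analogue is defined on a tree, mirroring the phylogenetic case. The null
model shuffles species labels across the tips — one pool-wide permutation
per iteration, applied to every quadrat simultaneously, so the null
preserves species abundance, frequency, occurrence and the cross-quadrat
correlation structure. Indices are sign-flipped z-scores:

    NRI      = -1 (MPD_obs - mean MPD_null) / sd MPD_null
    SES PW   = -1 (PW_obs  - mean PW_null)  / sd PW_null

positive = clustering, negative = overdispersion. Quadrats with fewer than
two species are undefined (excluded from aggregates, counted); a zero null
sd (e.g. a star tree, where all shuffles are equivalent) yields index 0
with a degeneracy flag. Quadrats are aggregated by the sign of their RLQ
axis-1 score (mean per side), tested against zero with a two-sided
one-sample t-test and, because the indices are spatially autocorrelated,
with the intercept test of an intercept-only SAR error model on each
side's sub-lattice; both p-values are reported since neither test is
uniquely implied by the design.

The implementation was cross-validated against `picante::ses.mpd`
(`taxa.labels` null, abundance-weighted): indices agree to Monte-Carlo
precision. (The conspecific-exclusion denominator is a per-quadrat
constant under tip shuffles, so it cancels exactly in the z-score.)

## Spatial machinery

Quadrat grids are half-open tilings `[x, x+s)` from the plot origin, so a
20-ha (500 x 400 m) plot yields exactly 2000/500/80/20 quadrats at
10/20/50/100 m. Neighbours are queen-contiguous (edge or corner), binary,
row-standardized where weights are needed; "first-order neighbour" admits
either rook or queen and queen is the default (rook is available). Moran's
I uses `I = (n/W..) z^T W z / z^T z` with a two-sided permutation test
around the null expectation `-1/(n-1)`. The MEM basis is the
eigendecomposition of the doubly-centered binary adjacency, retaining
positive-eigenvalue vectors (positive spatial autocorrelation — the scale
of filtering gradients, not fine-scale repulsion); the full non-trivial
basis is available via `keep="nonzero"`. Environment generated at 10 m is
carried to coarser scales by averaging constituent quadrats.

The SAR error model `y = mu + u, u = rho W u + eps` is fit by profile
maximum likelihood with the log-determinant from the eigenvalues of `W`
(real, because row-standardized `W` is similar to a symmetric matrix). It
matches a brute-force multivariate-normal likelihood maximization to four
decimals. A caution for interpreting its null behaviour: the exact ML
estimate of `rho` on a 10x10 queen lattice has a sampling sd near 0.19, so
apparently "large" `|rho|` on small lattices is ordinary sampling noise;
the estimator is unbiased and tightens as the lattice grows (sd ~0.09 at
n = 400).

## Distances and ordinations

Trait distances are Gower: mean over traits of `|x_i - x_j| / range`,
pairwise-skipping missing values, after the natural-log transform (below).
Species pairs sharing no measured trait are an error; species missing from
the trait table simply drop out of trait-dependent analyses at alignment.
PCoA applies Gower double-centering; when negative eigenvalues exceed
`1e-8 x max|eigenvalue|`, the Cailliez constant (largest real eigenvalue
of the standard 2n x 2n companion matrix) is added to off-diagonal
distances and the result is flagged — keeping all axes usable as
quantitative pseudo-traits. Ultrametric trees produce Euclidean cophenetic
distances, so phylogeny-PCoA never needs correction. The trait dendrogram
is UPGMA (average linkage) on the Gower matrix.

**Log transform totality.** Environment and trait tables are natural-log
transformed before distances and ordination. Real soil variables are
positive, but the rule must be total: strictly positive columns use
`log x`; columns dipping into `(-1, 0]` use `log1p`; columns reaching -1
or below (standardized synthetic fields do) are shifted to
`log(x - min + 1)`. The rule applied per column is logged and recorded in
the run manifest.

## The synthetic generator

The generator emulates the study system — a 20-ha rectangular stem map
with a few hundred taxa — with a known assembly rule so every downstream
statistic has ground truth:

- **Phylogeny**: pure-birth (Yule) tree, Exp(k) waiting times between
  splits plus an Exp(n) terminal hold, depth scaled to 1.
- **Traits**: Brownian motion on the Pagel-lambda-transformed tree
  (`signal_lambda` = 1 full signal, 0 independent), each trait
  standardized across species.
- **Environment**: Gaussian random fields with exponential covariance
  (`env_range_param`, default 50 m — mesoscale soil patchiness) on the
  10 m grid, standardized per field.
- **Regional abundances**: the expected Fisher log-series rank-abundance
  curve with alpha = 10, which puts ~half the stems in the top ~1% of
  species — tropical-plot-like dominance that deliberately stresses the
  abundance-weighted statistics. (i.i.d. log-series draws cannot reach
  this dominance; the rank-curve construction can.)
- **Assembly**: each individual draws its species from the regional curve
  and its quadrat with probability proportional to
  `exp(-filtering_strength (trait1_sp - env1_quadrat)^2)`, then a uniform
  position within the quadrat. `filtering_strength = 0` is neutral
  placement. Exactly one trait-environment pair carries the niche signal;
  all other traits and fields are nuisance dimensions, which makes
  parameter recovery unambiguous.

Defaults are a 500 x 400 m plot, 400 species, 50,000 stems, 10
environmental variables, 11 traits, `signal_lambda = 0.5`,
`filtering_strength = 5`.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: dispersal limitation and conspecific clumping
(placements are independent), topographic structure in the environment
(fields are stationary and isotropic), trait measurement error and
intraspecific variation, correlated niche axes (one trait filters), and
demography (a single static census).

## Calibration and recovery behaviour

Simulation suites in `tests/test_acceptance.py` establish, at sizes chosen
to keep the default run fast: the combined model-2+4 test holds its size
(rejection ~0.03-0.04 at nominal 0.05 over 500 neutral assemblies of ~100
sites x 30 species, 199 permutations); NRI standardized against its own
tip-shuffle null is a z-score (mean ~0.08, sd ~1.07 over 500 seeds); and
under strong filtering with fully conserved traits (lambda = 1,
filtering_strength = 30, 200 sites, 100 species) the planted niche pair is
detected in every seed and both RLQ axis sides show positive mean NRI in
~83% of seeds. The shortfall from 100% in the last figure is not
estimation noise: some tree/trait draws genuinely place similar trait
values in distant clades (trait convergence), producing one-sided
overdispersion even under strong filtering — the same decoupling of
functional from phylogenetic distance the empirical literature reports.

## Known limitations

- Quantitative variables only (the fourth-corner chi-square/eta-square
  forms for categorical data are not implemented).
- The SAR model is intercept-only — a spatially corrected test of a mean,
  not a general regression.
- MEM retention ignores negative-eigenvalue (repulsion) structure by
  default.
- Single census; no temporal dynamics.
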