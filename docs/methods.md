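# Methods

This note documents the statistical models implemented in `ecoassembly`,
the design decisions taken where the field's conventions diverge, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Null-model process partitioning

For a pair of communities *i, j* with relative abundances *f* and a
cophenetic distance matrix *d* over taxa,

βMNTD(i,j) = ½ [ Σ_k f_ik · min_{l∈j} d(k,l) + Σ_l f_jl · min_{k∈i} d(l,k) ],

where a taxon present in both communities contributes zero to its own
nearest-taxon term.  The null model shuffles taxon labels across **all**
tips of the tree (equivalently, applies a random permutation to the rows
and columns of the cophenetic matrix); abundances are untouched.  βNTI
is the z-score of the observation against this null.  Pairs whose null
standard deviation falls below 10⁻¹² (identical communities; trees whose
tip distances are label-invariant, e.g. a star tree) are flagged
*degenerate*, reported as missing, and classified by the taxonomic null
alone rather than aborting the run.

The Raup-Crick null preserves each sample's observed richness and total
read count: species are drawn without replacement with probability
proportional to their occurrence frequency across samples, each drawn
species receives one read, and the remaining reads are assigned
multinomially in proportion to metacommunity relative abundance among
the drawn species.  RC = 2·[(#null < obs) + ½(#null = obs)]/n_null − 1.
For speed, one null community per sample is drawn per iteration and the
iteration's nulls are compared pairwise, so all pairs share null draws
within an iteration; the marginal null distribution of each pair is
unchanged, and 999 iterations on 40 × 300 complete in seconds.

Classification: βNTI > 2 → variable selection; βNTI < −2 → homogeneous
selection; otherwise RC > 0.95 → dispersal limitation, RC < −0.95 →
homogenizing dispersal, else undominated.  SDER is the summed selection
fraction divided by the dispersal-limitation fraction; a zero
denominator is reported as infinite rather than raising, because
regimes without any dispersal-limited pairs are a legitimate outcome.

### Phylogenetic-signal pretest

βNTI is only interpretable if close relatives share environmental
preferences.  The pretest computes each taxon's niche value as the
abundance-weighted mean of each standardized environmental variable
across samples, takes Euclidean distances between taxon niche vectors,
and correlates them with cophenetic distances in a Mantel correlogram.
Two sign conventions coexist in the literature for Mantel correlograms:
the *association* convention reports the correlation between the
response matrix and the class-membership indicator directly (positive =
response elevated in that class), while the *autocorrelation* convention
negates it so that within-class similarity reads as positive.  Both are
implemented behind a `convention` flag; the phylogenetic-signal test
uses the autocorrelation convention (signal present = positive,
significant r in the shortest distance classes), and the
βNTI-vs-environment correlograms use the association convention.
A single Brownian trait on a deep phylogeny yields weak Mantel
correlations even under perfect conservatism; the pretest therefore
gains most of its power from multi-variable niche vectors.

## Sloan neutral model

Occurrence frequency is predicted as f(p̄) = 1 − BetaCDF(d; Nmp̄,
Nm(1−p̄)) with N the mean reads per sample and detection limit d = 1/N
(one read at mean depth; the convention of the standard least-squares
implementation).  m is fitted by bounded scalar minimization of the sum
of squared occurrence deviations; the binomial comparison model
f = 1 − BinomCDF(⌈dN⌉−1; N, p̄) has no free parameters.  Both models use
the least-squares AIC n·ln(SS/n) + 2k (k = 1 vs k = 0) so they are
directly comparable.

**Known estimator bias.** On data generated exactly from the stationary
law of the migration-drift process (see below), the fitted m is biased
upward — about +15% at m = 0.05 and +35% at m = 0.25.  The cause is the
threshold approximation of detection: the model treats a taxon as
detected when its relative abundance exceeds d = 1/N, whereas the true
detection kernel of an N-read sample is 1 − (1 − p)^N, which crosses ½
at p = ln 2/N ≈ 0.69/N.  Fitted m values are therefore best read as a
relative index of dispersal limitation (their rank order across
communities is preserved; validated over m ∈ {0.01, 0.05, 0.25}),
not as an absolute migration probability.  We keep the standard
d = 1/N convention rather than recalibrating, for comparability with
published fits.

Levins niche breadth B = 1/Σᵢ Pᵢ² uses the distribution of a taxon's
reads across samples; Bcom is the unweighted mean of B over taxa present
in a sample (an abundance-weighted variant is available).  Dispersal
ability D averages, over all sample pairs, the mean of the two samples'
read fractions belonging to shared taxa; the one-line verbal definition
in the literature admits a min-of-two-sides reading, which is provided
as a sensitivity variant.

## Spatial statistics

PCNM: distances beyond the longest minimum-spanning-tree edge *t* are
replaced by 4*t*, the matrix is Gower-double-centered and
eigen-decomposed; positive-eigenvalue axes scaled by √λ are the spatial
predictors.  dbRDA regresses the principal coordinates of the
(Bray-Curtis) dissimilarity matrix on predictors; negative PCoA
eigenvalues are discarded (no Lingoes/Cailliez correction — the simplest
convention, adequate because R² is a ratio of inertias on the retained
axes).  Adjusted R² is Ezekiel's 1 − (1 − R²)(n − 1)/(n − p − 1).

Forward selection is greedy on adjusted-R² gain with two stopping rules:
the candidate's permutation p must be below α, and the cumulative
adjusted R² may not exceed the full model's.  The bound is not applied
to the first variable: with few candidates, sampling noise in the
Ezekiel penalty can place a single strong predictor above the
noise-diluted full model, and the bound's purpose is to stop
accumulation of spurious gains, not to return empty models.

Variation partitioning computes adjusted R² for the seven subset models
of three predictor sets and derives the seven fractions by
inclusion-exclusion (exact to 10⁻⁹ by construction; verified in tests).
Overlapping or duplicated sets are handled by reducing each subset model
to a maximal linearly independent column set.  Pure fractions may be
slightly negative; interpret as zero.

NMDS uses non-metric MDS (20 restarts, 300 iterations) and reports
Kruskal stress-1 computed through isotonic regression of embedding
distances on observed dissimilarities.  Environmental fitting reports,
per variable, the squared multiple correlation with the site scores and
a permutation p; variables with pairwise |Spearman ρ| > 0.7 are
pre-filtered (first kept wins), and the key-variable flag is R² > 0.2
with p < 0.01.

Mantel-family permutation tests shuffle sample labels jointly on rows
and columns and use p = (1 + exceedances)/(1 + permutations).  MRM
regresses the unfolded response triangle on predictor triangles with
two-sided coefficient tests; the two-stage variant refits on predictors
with p < 0.05.

## TITAN

Candidate change points are the unique gradient values leaving at least
`min_side` (default 5) samples on each side; the left group is x ≤ c.
IndVal is the Dufrêne-Legendre group-equalized form: (group mean
abundance / sum of the two group means) × group occurrence frequency ×
100.  The taxon's direction and change point maximize IndVal over
candidates and sides; z standardizes the observed maximum against
gradient-permutation maxima of the same side.  Because the observed
statistic involves selecting the better side, the taxon-level p-value
compares the side-free maximum against its permutation distribution —
using the per-side null would be anticonservative (this is validated by
a uniformity test at 200 null replicates).  Bootstrap resampling of
samples yields purity (fraction agreeing in direction) and reliability
(fraction with permutation p ≤ 0.05); the filter is purity ≥ 0.95 and
reliability ≥ 0.95.  Community curves tally filtered taxa's z at their
observed change points; the sum(z−) and sum(z+) argmaxes are the lower
and upper community thresholds.  Under negative-binomial read noise the
curve peaks drift outward by up to a few tenths of a gradient unit
(extreme draws pull the optimal split toward the tails); the median of
filtered change points is the more robust estimator of a shared
threshold and is what the validation checks.

## Co-occurrence networks

Association scores are Spearman's ρ and Bray-Curtis similarity between
taxon abundance profiles.  ReBoot significance: the permutation null
shuffles one taxon's counts across samples and renormalizes every
sample's composition (easing compositional artifacts) before re-scoring;
the bootstrap resamples samples with replacement; the p-value is the
two-sided Gaussian tail of the mean null score under N(bootstrap mean,
bootstrap sd).  Brown's method combines the two dependent p-values via
X = −2(ln p₁ + ln p₂) ~ c·χ²(k) with c = Var/2E, k = 2E²/Var, E = 4 and
Var = 8 + 2·cov; the covariance is estimated empirically across all
candidate edges from the paired −2 ln p values (it is not identifiable
from a single pair), clipped to |cov| ≤ 4.  At zero covariance the
method reduces exactly to Fisher's.  Benjamini-Hochberg q ≤ 0.05 and
|ρ| above the RMT threshold define the edge set.

The RMT threshold scans |ρ| cutoffs (0.50–0.95, step 0.01), takes the
largest connected component of each thresholded adjacency, unfolds its
eigenvalue spectrum with a Gaussian-smoothed empirical CDF (Silverman
bandwidth), and tests the nearest-neighbor spacing distribution against
the Poisson (exponential) law by χ² on 20 bins over [0, 3]; the chosen
threshold is the lowest at which Poisson statistics fit (p > 0.05) and
keep fitting at all higher thresholds — the transition from
GOE-correlated noise to modular signal.  If no scanned threshold leaves
a component of ≥ 20 nodes, a configurable default (0.74) is used with a
warning.

Modules are detected by fast-greedy (CNM) modularity maximization on
the positive-edge subgraph — modularity is not defined for negative
weights, so negative edges are retained in the graph and its reports
but excluded from clustering.  The greedy algorithm can undershoot the
optimal Q on sparse chain-like graphs; on modular graphs it matches the
brute-force optimum (verified exhaustively on ≤ 8 nodes).  Dominant
modules hold > 10% of nodes; a module eigengene is PC1 of the z-scored
member profiles, sign-fixed to correlate positively with the mean member
abundance.  Local networks are induced subgraphs on the taxa present in
each sample, summarized by density, clustering, centrality means,
modularity, diameter, mean path length and node/edge counts;
collinearity-filtered, standardized features give a per-sample Euclidean
topology distance that can be regressed on geographic distance and
passed to the two-stage MRM.

## Synthetic metacommunities

The generator defines the conditions under which every method is
validated.

* **Phylogeny**: pure-birth (Yule), ultrametric, depth scaled to 1.
* **Sites**: uniform in a 650 km square (the span of a large regional
  soil survey); environmental variables are standard-normal GP draws
  with a configurable correlation length (0 = environment independent of
  space; hundreds of km = environment and space confounded).
* **Niche optima**: Brownian motion on the tree blended with iid noise,
  trait = √λ·BM + √(1−λ)·ε; λ = 1 gives fully conserved niches.
* **Regional pool**: lognormal abundances (σ = 1.5), a realistic
  amplicon-survey skew.
* **Neutral regime**: each site's composition is drawn from the
  stationary law of the Hubbell death-replacement process with migration
  m — a Dirichlet(N·m·γ) pool, whose marginals are exactly the beta
  distribution the Sloan model fits — followed by a multinomial read
  draw.  A finite Moran chain (`sample_neutral_community`, numba-
  compiled, default 10 sweeps) is exposed for studying transient drift;
  it is not used for the regime tables because a truncated chain sits
  between its initial condition and stationarity, which under-disperses
  local pools and makes the generated migration rate ill-defined.
* **Selection regime**: the pool is re-weighted per site by
  exp(−(env − optimum)²/2σ²) over the selected variables and
  renormalized before sampling; σ → ∞ recovers the neutral m = 1 limit.
* **Dispersal-limited regime**: independent stationary pools at low m
  are mixed with the spatial kernel exp(−κ·d/d̄); large κ isolates
  sites, raising RC > 0.95 fractions and steepening distance decay.
* **Gradient taxa**: hard or logistic step responses at known change
  points, negative-binomial (size 1) reads plus a uniform background
  rate — the overdispersion typical of amplicon counts.
* **Correlated blocks**: within-block latent factor loading √ρ on
  log-normal rates, Poisson reads; block identity is the module truth.

Defaults mirror a two-domain rhizosphere survey: 78 → 40 samples and
10⁴ → 300 taxa scaled down for test budgets, reads 2000 per sample,
migration m = 0.25 (bacteria-like) and 0.014 (fungi-like) for the
regime contrasts.  What the generator does **not** emulate: sequencing
error and chimeras, taxonomy, variable read depth, compositional bias
between domains, temporal dynamics, and true species interactions
(block correlations are driven by shared latent environments, not
mechanistic interactions).  Passing tests therefore demonstrate that
the estimators recover known structure of this idealized data-generating
process, not that real communities satisfy its assumptions.

## Numerical choices

* Permutation p-values use the add-one convention everywhere; p is
  never 0.
* βNTI degeneracy cutoff: null sd < 10⁻¹².
* Rarefaction is multivariate-hypergeometric with per-sample substreams
  spawned deterministically from one seed; pipelines are reproducible
  bit for bit from config + seed.
* Sloan m is optimized on (10⁻⁶, 1] by bounded Brent; PCNM/PCoA
  eigenvalues below 10⁻⁹ of the maximum are treated as zero.
* Correlogram classes are equal-width bins with Sturges' count by
  default; Holm correction across classes.
* Validation problem sizes (40 × 300 × 2000 with 999 nulls for regime
  contrasts; 100 × 300 × 2000 for neutral fits; 50-sample gradients;
  2-3 blocks × 10-15 taxa networks) were chosen as the smallest at which
  the contrasts of interest are comfortably resolved.

## Known limitations

* The Sloan m estimate carries the upward detection-threshold bias
  quantified above; use it comparatively.
* CNM modularity is greedy; sparse non-modular graphs may cluster below
  the optimum.
* The RC null's shared-draw scheme introduces weak dependence between
  pairs within one iteration; per-pair summaries are unaffected, but
  joint statistics across pairs of pairs would be.
* TITAN community-curve peaks are quantized to observed candidate values
  and drift outward under heavy overdispersion; prefer the median
  change point for point estimation.
* envfit's linear vector fitting understates strongly curved gradients,
  as in the R implementations it mirrors.
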