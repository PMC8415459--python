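# ecoassembly

Community-assembly analysis for microbial metacommunities.

Soil bacteria and fungi assemble into local communities through a mix of
deterministic processes (environmental selection by pH, nutrients,
climate) and stochastic ones (dispersal, ecological drift).  This
package implements the full statistical toolkit used to disentangle
those processes from amplicon survey data — an OTU count table, a
phylogeny and per-site environmental metadata — and a synthetic
metacommunity generator with known ground truth to validate every step.
It is aimed at microbial ecologists comparing assembly processes across
taxonomic groups (e.g. bacteria vs fungi in a rhizosphere survey) or
across environmental gradients.

## What it computes

**Null-model process partitioning.** For every pair of communities:

- βMNTD, the abundance-weighted mean phylogenetic distance from each
  taxon to its nearest relative in the other community, and
  **βNTI** = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null), where the
  null shuffles taxon labels across the tips of the tree.
  βNTI > +2 ⇒ variable selection; βNTI < −2 ⇒ homogeneous selection.
- **RC_Bray**, Raup-Crick on Bray-Curtis, rescaled to [−1, 1], with a
  null preserving each sample's richness and total reads (species drawn
  by metacommunity occurrence frequency, reads assigned by metacommunity
  relative abundance).  For pairs with |βNTI| ≤ 2: RC > 0.95 ⇒ dispersal
  limitation, RC < −0.95 ⇒ homogenizing dispersal, else undominated.
- **SDER**, the selection / dispersal-limitation ratio, from the pair
  fractions (null-model route) or from pure variation-partitioning
  fractions (VPA route), plus a phylogenetic-signal pretest
  (niche distance vs phylogenetic distance Mantel correlogram).

**Sloan neutral model.** Occurrence frequency predicted from mean
relative abundance, f(p̄) = 1 − BetaCDF(d; N m p̄, N m (1 − p̄)), with a
single migration parameter m fitted by least squares; generalized
R² = 1 − SS_err/SS_tot and an AIC comparison against the parameter-free
binomial (random-subsampling) model.  Plus Levins niche breadth
B = 1/ΣP², its community mean Bcom, and pairwise-sharing dispersal
ability D.

**Spatial statistics.** Bray-Curtis β-diversity, distance-decay slopes,
Mantel / partial Mantel / Mantel correlograms / MRM, PCNM spatial
eigenvectors, dbRDA with Ezekiel-adjusted R², forward selection with the
double stopping rule, three-set variation partitioning
(soil / climate / space), and NMDS with environmental vector fitting.

**Community thresholds (TITAN).** Per-taxon change points along an
environmental gradient via indicator values (IndVal), permutation
z-scores and bootstrap purity/reliability; community-level thresholds as
the peaks of the filtered sum(z−) and sum(z+) curves.

**Co-occurrence networks.** Spearman + Bray-Curtis association scores
with ReBoot significance (renormalized permutation null vs bootstrap
distribution), Brown's combination of the two p-values, BH correction,
a random-matrix-theory correlation threshold, fast-greedy modules with
modularity Q, module eigengenes, and per-sample local-network topology.

**Synthetic metacommunities.** A generator with four regimes — neutral
(migration-drift stationary), selection (Gaussian niche filtering with
phylogenetically conserved optima), dispersal-limited (drifted local
pools mixed by a spatial kernel), and mixed — plus gradient-response
and block-correlation generators, all emitting ground truth.

## Worked example

`examples/01_process_partitioning.py` simulates 24 sites × 150 taxa
under environmental selection with fully conserved niches, then runs the
two-null-model classification:

```
regime simulated: selection (sigma = 0.5)
community pairs classified: 276
  variable_selection        51.4 %
  homogeneous_selection      0.0 %
  dispersal_limitation      10.1 %
  homogenizing_dispersal    21.0 %
  undominated               17.4 %
SDER (selection / dispersal limitation): 5.07
RC-only stochastic fraction (|RC| > 0.95): 69.2 %
```

Half the community pairs sit above βNTI = +2 — the phylogenetic
signature of spatially variable selection — and selection outweighs
dispersal limitation five-fold (SDER 5.07).  A dispersal-limited run of
the same size inverts the pattern (dispersal limitation ≫ selection,
SDER ≪ 1).  `examples/02_neutral_model.py` fits the neutral model to a
drift-assembled metacommunity:

```
generator migration rate m = 0.25
fitted m = 0.330  (N = 2000 reads, detection limit d = 5.00e-04)
generalized R^2 = 0.962
AIC neutral = -1680.5, AIC binomial = -952.0 -> neutral model preferred
community niche breadth Bcom: mean 31.5 over 60 samples
community dispersal ability D = 0.920  (1 = all samples share all taxa)
```

The occurrence-abundance curve is captured almost perfectly
(R² = 0.96) and the neutral model beats random subsampling decisively;
the fitted m tracks the generator's migration rate (see
`docs/methods.md` for the known upward bias of this estimator).  The
other examples cover variation partitioning, TITAN thresholds,
network inference and the Mantel family.

There is also a thin CLI over the same stages:

```bash
ecoassembly simulate --regime selection --seed 1 --out-dir run/
ecoassembly all --config config.yml --seed 1 --out-dir run/
```

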