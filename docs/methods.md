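# Methods

This note documents the models and procedures implemented in `bentheco`,
the conventions fixed where the literature is ambiguous, what the synthetic
data do and do not emulate, and the numerical choices that matter.

## Scope and data model

The pipeline starts at the OTU count table. Read quality control, chimera
removal, 97%-similarity clustering, and taxonomy assignment are upstream
concerns of other tools; their products — a samples × OTUs integer matrix,
PR2-style lineage strings, a rooted Newick phylogeny of the OTUs, and a
per-sample environmental table — are this package's inputs. All tables are
UTF-8, LF-terminated TSV written at full float precision, so write→read
round-trips are exact. Unrooted trees (basal multifurcation) are
midpoint-rooted on load, because UniFrac, Faith's PD, and βMNTD all require
a root; missing branch lengths are imputed as 0 with a logged warning
rather than rejected, since exported trees frequently omit internal edge
lengths. A lineage-exclusion filter (`exclude_lineages`) removes
non-target groups (e.g. Bacteria, Archaea, plastidial, Metazoa reads)
before analysis; its position relative to any upstream singleton filtering
is the caller's choice, since conventions differ.

## Diversity

* **Rarefaction** draws once, without replacement (multivariate
  hypergeometric), to a fixed depth with a caller-supplied seed. Samples
  below the target depth are dropped with a warning — a survey rarefied "at
  the lowest sequence number" keeps all its samples, but synthetic or
  subset data may not. Averaging over repeated draws is deliberately not
  offered; a single seeded table keeps every downstream statistic
  reproducible.
* **Shannon entropy** is reported in bits (log base 2), the historical
  QIIME 1 default. Richness counts OTUs with non-zero counts.
* **Faith's PD** uses the rooted convention: the branch path from a
  sample's tips up to the root is included, so a single-taxon sample
  already has positive PD and the full tip set recovers the tree's total
  branch length. The unrooted convention differs by one root-path constant;
  the choice is fixed here and pinned by tests.
* **Bray-Curtis** follows BC = 1 − 2Σmin/(Σx+Σy); a pair of all-zero
  samples is defined as distance 0 with a warning. **Unweighted UniFrac**
  (presence/absence; unique / total branch length) is delegated to
  scikit-bio's implementation against hand-worked four-leaf oracles.
* **PCoA** double-centers the squared distances (Gower), takes the
  symmetric eigendecomposition, and returns coordinates only on axes with
  eigenvalues > 1e-10. Negative eigenvalues — expected for non-Euclidean
  dissimilarities like Bray-Curtis — are reported but excluded from both
  coordinates and the proportion-explained denominator.

## Permutation statistics

ANOSIM, simple Mantel, and partial Mantel are implemented in-package with
explicit `numpy.random.Generator` seeding (library equivalents do not
accept a seed, which would break whole-pipeline reproducibility); their
statistics are cross-checked against scikit-bio in the test suite. All
permutation p-values use the +1 correction, p = (#extreme + 1)/(n_perm + 1),
and are therefore bounded below by 1/(n_perm + 1). Mantel tests are
one-tailed for positive association by default — the ecological convention
when asking whether community dissimilarity increases with spatial or
environmental distance — with a two-tailed option. The partial Mantel test
residualizes both matrices on the control entrywise (OLS on the lower
triangle, reflected back to a symmetric matrix) and permutes the
residualized first matrix; when a matrix is explained by the control to
rounding error, its partial correlation is defined as 0 rather than letting
numerical noise produce an arbitrary value. Mantel permutation counts
default to 9,999; ANOSIM to 999. SIMPER decomposes the mean between-group
Bray-Curtis into per-OTU terms |xᵢ−yᵢ|/Σ(x+y) averaged over between-group
sample pairs; the terms sum exactly to the mean between-group dissimilarity
(tested at 1e-10) and are intended to run on the rarefied table.
Environmental distance z-scores each variable (dropping zero-variance
columns) before Euclidean distance; geographic distance is haversine with
Earth radius 6,371 km.

## Assembly null models

**βMNTD** (abundance-weighted by default) is, for a pair of communities,
the mean over taxa of the patristic distance to the nearest taxon in the
partner community, weighted by within-sample relative abundance and
averaged over both directions. **βNTI** standardizes the observed βMNTD
against 999 randomizations that shuffle OTU labels across the tips of the
phylogeny — the "taxa shuffle" of the standard null-model framework, which
preserves the count table and tree shape while destroying the
taxon–phylogeny association. Pairs with zero null standard deviation
(identical presence sets, whose βMNTD is invariant under relabeling) are
flagged NaN and excluded from partition denominators with their count
reported. The implementation permutes rows/columns of the precomputed
patristic matrix instead of relabeling the tree, and was verified to match
R `picante` (`comdistnt` + `taxaShuffle`) exactly on βMNTD and
consistently on the standardized scores.

**RC_bray** compares each pair's observed Bray-Curtis to 999 null
communities that preserve the pair's per-sample richness and total
abundance: taxa enter with probability proportional to their occurrence
frequency across samples (one individual each), remaining individuals are
assigned multinomially by regional relative abundance, and
RC = ((#null < obs) + ½·#ties)/999 rescaled to [−1, 1]. Two implementation
choices matter. First, each null round redraws every sample once and
compares all pairs simultaneously; a pair's null values are still
independent draws from its own pairwise null, but the cost is
O(n_null·n_samples) community draws instead of O(n_null·n_pairs). Second,
weighted sampling without replacement uses the exponential-keys method
(smallest k values of Exp(1)/wᵢ), which is equivalent in distribution to
successive weighted draws but vectorizes. The regional pool (occupancy
weights and regional abundances) defaults to table-derived estimates and
can be supplied explicitly when a wider species pool is known — the
null-calibration benchmark uses this to score null-process pairs against
the exact pool they were drawn from.

**Partition.** βNTI > 2 → variable selection; βNTI < −2 → homogeneous
selection; otherwise RC > 0.95 → dispersal limitation, RC < −0.95 →
homogenizing dispersal, else undominated. Ties at exactly |βNTI| = 2 or
|RC| = 0.95 fall on the stochastic/undominated side, and the selection
test precedes the dispersal test — both conventions are arbitrary at
measure-zero boundaries but deterministic and tested. The undominated
class is often loosely called "drift"; the output label is `undominated`
with that alias documented. The partition is computed over all aligned
sample pairs in one pooled analysis, on the rarefied table by default.

## Co-occurrence networks

SparCC estimates basis correlations from log-ratio variances
t_ij = var(log xᵢ/xⱼ), which are invariant to per-sample totals. Under the
sparsity assumption the basis variances solve the linear system
Σⱼt_ij = (d−2)ωᵢ² + Σⱼωⱼ², and r_ij = (ωᵢ²+ωⱼ²−t_ij)/(2ωᵢωⱼ), clipped to
[−1, 1]. The most correlated pair above the exclusion threshold (default
0.1) is iteratively removed from the system and the basis re-solved, up to
20 rounds; estimates are averaged over 20 Dirichlet posterior fraction
draws with unit pseudocount. These defaults follow the original method and
are all exposed.

Pseudo p-values default to a **permutation null** that shuffles each OTU's
counts across samples independently, destroying between-OTU association
while preserving marginals; two-sided p = (#{|r_null| ≥ |r_obs|}+1)/(n+1).
Bootstrap resampling of samples is available as an alternative but is not
the default because resampling preserves the observed correlations and
therefore is not a null — p-values under it cannot be calibrated.
Benjamini-Hochberg FDR is applied to the m = N(N−1)/2 unique-pair vector,
and the edge rule is |r| strictly greater than 0.4 AND adjusted p strictly
below 0.01 (raw p available by flag). Note that with B permutations the
smallest achievable raw p is 1/(B+1), so after BH adjustment at least
~0.01·m pairs must sit at the floor for any edge to pass an adjusted-p
gate of 0.01; sparse desk-scale simulations can legitimately yield empty
networks. Reported node counts follow the connected convention (isolated
nodes are not part of the graph). Diameter and average path length are
computed on the largest connected component with unweighted shortest
paths; modularity uses greedy modularity communities on the unweighted
graph. Nearshore/offshore (or any other) sample groupings are pipeline
configuration, not hard-coded station names.

## Synthetic surveys: what they emulate, and what they do not

The generator reproduces the *structure* of a bay-transect sediment
survey: 9 stations on a line at 2-km spacing (constant latitude, so
haversine distances match the nominal spacing), up to 5 one-cm sediment
layers per station, ~300 OTUs at 10,000 reads per sample — sizes chosen so
999-randomization null models complete in minutes on one CPU. Metadata
follow seaward gradients with noise: water depth 8→35 m, bottom
temperature 30.5→26 °C, salinity 32.6→34.2, seven metals declining ~40%
seaward from typical coastal-sediment baselines (e.g. Zn 110, Cr 60, Cu 25
mg/kg), and Dirichlet grain-size fractions shifting from mud nearshore to
sand offshore, summing to 100 by construction.

Communities are assembled from a lognormal species-abundance distribution
shaped by the regime:

* **selection** — a Gaussian niche filter exp(−(z−env)²/2σ²) on a single
  Brownian trait simulated along the (ultrametric, unit-height) Yule tree.
  The niche axis is standardized to the realized trait SD so that
  environment values mean the same thing across Brownian realizations.
* **dispersal_limitation** — per-station species pools mixed with an
  exp(−κ·distance) immigration kernel from partially disjoint regional
  pools (each holding a `pool_occupancy` fraction of OTUs), yielding
  distance decay of similarity without phylogenetic structure.
* **drift** — one shared pool, independent multinomial resampling per
  sample, no further structure.
* **mixed** — the niche filter applied on top of dispersal-limited pools.

Except under pure drift, expected profiles also receive per-sample
lognormal jitter and a stochastic colonization (lottery recruitment) mask.
This turnover is essential, not cosmetic: without it, a 10,000-read sample
from a 300-OTU pool contains nearly every OTU, presence structure carries
no information, and βMNTD's null variance collapses for identical-presence
pairs. The defaults (colonization 0.6, jitter SD 0.5, SAD σ 1.0) put
per-sample richness at a realistic one- to two-thirds of the pool.

The named regime presets fix the study conditions used in validation. The
`homogeneous_selection` preset deserves explanation: detecting βNTI < −2
requires the constant environment to favour a phylogenetically coherent
guild, but whether any coherent clade happens to sit near an arbitrary
fixed optimum is luck of the Brownian draw — at 300 OTUs roughly half of
realizations place no tight clade there, and the regime silently degrades
to drift. The preset therefore sets `coherent_guild=True`: the environment
is placed at the niche value (grid search over ±2.5 SD) that maximizes
phylogenetic coherence of the selected guild, measured as the
filter-weighted mean nearest-neighbour patristic distance among the 30
most-favoured OTUs. This is a deterministic function of the simulated tree
and traits and encodes the regime's own premise — a consistently stressful
habitat favouring one conserved clade (as anoxia favours particular
protist lineages). Regime-recovery benchmarks additionally pool sample
pairs over 3 replicate surveys (fresh tree and traits each) to average the
remaining tree-realization variance.

What the generator does **not** emulate: sequencing error, PCR/primer
bias, chimeras, compositional coupling between regimes (e.g. selection
acting on metals specifically), temporal dynamics, or realistic taxonomy
(lineages in synthetic taxonomies are labels, not biology). Passing the
recovery benchmarks therefore shows that the statistical machinery detects
the processes it targets when those processes generated the data — not
that any particular field dataset was assembled by them.

## Validation and problem sizes

The test suite checks every metric against an independent route:
brute-force double loops for Bray-Curtis, βMNTD, and network topology
(max |Δ| < 1e-10 over hundreds of random small instances); closed forms for
Shannon, PD, UniFrac, Spearman, haversine, and Benjamini-Hochberg;
scikit-bio as an external oracle for ANOSIM/Mantel statistics and PCoA;
and R picante (during development) for βMNTD/βNTI. Null self-calibration
uses 8 replicate 8-sample × 100-OTU tables (224 pairs) for βNTI coverage
of [−2, 2], and 210 independent null-process pairs for the RC_bray mean.
SparCC recovery uses the planted-correlation design at the stated 200
samples; the identity-basis (compositional-bias) check runs at 2,000
samples because a log-ratio variance estimator's per-pair sampling noise
is ~√(2/n) ≈ 0.1 at n = 200, which would swamp the bias being tested —
at n = 2,000 spurious correlations sit below 0.08. Regime recovery runs
each preset at the full 9 × 4 × 300 × 10,000 design with 999 nulls,
pooled over 3 replicates. End-to-end determinism is verified by running
the whole pipeline twice at one seed and comparing outputs byte for byte;
every stage derives its own sub-seed by hashing the global seed with the
stage name, so adding or disabling a stage never perturbs the others.

## Known limitations

* βNTI's power to detect homogeneous selection at 300-OTU scale is
  intrinsically marginal; the coherent-guild construction and replicate
  pooling address the scenario design, not the metric's power on real
  data, which benefits from far larger pools.
* The RC_bray pooled-null scheme ties the per-round draws of different
  pairs together; per-pair marginal distributions are exact, but joint
  statements across pairs (e.g. the covariance of two pairs' RC values)
  are not what fully independent per-pair nulls would give.
* SparCC correlations carry ~1/√n sampling noise that no amount of
  Dirichlet averaging removes; at 36-sample survey scale the |r| > 0.4
  threshold is near the noise floor, and FDR-adjusted p < 0.01 with ≤100
  permutations can only be cleared when many pairs share the floor.
* The partial Mantel residual-permutation test is one standard choice
  among several; none is uniformly best under heteroscedastic distance
  relationships.
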