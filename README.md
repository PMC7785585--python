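# bentheco

Community-ecology analysis of benthic microbial-eukaryote metabarcoding
data: diversity estimation, multivariate community statistics, null-model
quantification of assembly processes, and compositionality-robust
co-occurrence networks — plus a synthetic-data generator that produces
whole surveys with known ground truth.

The package is aimed at microbial ecologists working with OTU count tables
from sediment (or other environmental) amplicon surveys. It starts where
read processing ends: given a samples × OTUs count table, a rooted
phylogeny of the OTUs, taxonomy lineages, and per-sample environmental
metadata, it reproduces the downstream statistical workflow of a coastal
sediment transect study — nine stations across a bay, cored in 1-cm
sediment layers.

## What it computes

**Diversity.** Seeded rarefaction to a common depth; OTU richness, Shannon
entropy H = −Σ pᵢ log₂ pᵢ (bits), and Faith's phylogenetic diversity (sum
of branch lengths spanning a sample's taxa, rooted convention); Bray-Curtis
dissimilarity BC = 1 − 2Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ) and unweighted UniFrac;
principal coordinates analysis by Gower double-centering.

**Community statistics.** Spearman screens of alpha diversity and
taxon-group abundances against environmental variables; ANOSIM
R = (r̄_between − r̄_within)/(n(n−1)/4); SIMPER decomposition of
between-group Bray-Curtis into per-OTU contributions; simple and partial
Mantel tests with seeded permutations; great-circle geographic distances
and z-scored Euclidean environmental distances; distance-decay regression.

**Assembly processes.** For every sample pair, the abundance-weighted beta
mean nearest taxon distance (βMNTD), its standardized effect size βNTI
against 999 tip-label shuffles, and the abundance-based Raup-Crick metric
RC_bray against 999 richness- and abundance-preserving null communities.
Pairs are partitioned into five processes:

| condition | process |
|---|---|
| βNTI > 2 | variable selection |
| βNTI < −2 | homogeneous selection |
| \|βNTI\| ≤ 2, RC > 0.95 | dispersal limitation |
| \|βNTI\| ≤ 2, RC < −0.95 | homogenizing dispersal |
| \|βNTI\| ≤ 2, \|RC\| ≤ 0.95 | undominated ("drift") |

**Networks.** SparCC basis correlations from log-ratio variances (with
iterative strong-pair exclusion and Dirichlet posterior averaging),
permutation pseudo p-values, Benjamini-Hochberg FDR, thresholding at
|r| > 0.4 and adjusted p < 0.01, and topology metrics (degree, density,
diameter, clustering, modularity, path length, percent positive edges)
per habitat group.

**Synthetic surveys.** `bentheco.synthetic` generates Yule trees with
Brownian niche traits, transect metadata with seaward gradients (depth,
temperature, salinity, seven metals, grain-size fractions), and OTU tables
assembled under controllable regimes — niche selection, distance-decaying
dispersal limitation, pure drift, or a mixture — so every downstream stage
can be validated against known truth.

## Worked example

```python
from bentheco import ScenarioConfig, simulate_scenario, rarefy, alpha_diversity
from bentheco.assembly import quantify_assembly

data = simulate_scenario(ScenarioConfig(scenario="dispersal_limitation", seed=1))
table = rarefy(data.table, depth=10_000, seed=1)
print(alpha_diversity(table, data.tree).head(3))
pairs, partition = quantify_assembly(table, data.tree, n_null=999, seed=1)
print({k: round(v, 3) for k, v in partition.fractions.items()})
```

prints

```
  sample_id  richness   shannon         pd
0     Z1-L1       181  6.476399  50.771632
1     Z1-L2       171  6.461064  51.399329
2     Z1-L3       172  6.522351  50.754161
```

(per-sample OTU richness, Shannon entropy in bits, and Faith's PD in units
of tree branch length — about 180 of 300 OTUs and ~6.5 bits of evenness in
the first 1-cm layers at the innermost station), then

```
{'variable_selection': 0.017, 'homogeneous_selection': 0.011,
 'dispersal_limitation': 0.96, 'homogenizing_dispersal': 0.0,
 'undominated': 0.011}
```

— 96% of the 630 sample pairs are classified as dispersal limitation,
recovering the regime this survey was simulated under.

The same workflow runs from the shell:

```bash
bentheco simulate --scenario mixed --seed 1 --out survey/
bentheco run-all --config run.yml     # simulate -> rarefy -> diversity ->
                                      # stats -> assembly -> networks
```

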