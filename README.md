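# edaphonet

Soil-microbiome co-occurrence networks, diversity and multifunctionality
along erosion gradients.

Soil erosion strips topsoil, nutrients and moisture, and with them the
microbial communities that drive nutrient cycling. `edaphonet` is a
reusable analysis pipeline for amplicon studies of erosion gradients (or
any categorical soil-degradation gradient): given an OTU count table,
sample metadata describing a site × erosion-level × transect × plot design,
and a table of measured soil variables, it quantifies how microbiome
diversity and network complexity track overall soil functioning. It is
aimed at microbial ecologists who have OTU tables and soil chemistry in
hand and want the full downstream statistical layer in one tested package.

## What it computes

- **Soil multifunctionality (MF).** Each of 12 soil function variables
  (moisture, OC, TN, TP, NH₄⁺, NO₃⁻, AP, AK, MBC, MBN, Cm, Nm; pH is
  excluded as a log-scale quantity) is tested for normality (Shapiro–Wilk),
  log- or √-transformed toward normality where needed, rescaled to
  [0, 1] by (x − min)/(max − min), and averaged per plot:
  MF = (1/12) Σᵥ scaledᵥ.
- **Alpha diversity:** Shannon H = −Σ pᵢ ln pᵢ, observed species, and the
  abundance-based coverage estimator
  ACE = S_abund + S_rare/C_ace + (F₁/C_ace) γ², with C_ace = 1 − F₁/N_rare.
- **Beta diversity:** Bray–Curtis dissimilarities, ANOSIM
  (R = (r̄_between − r̄_within)/(n(n−1)/4) on midranks, permutation p,
  Bonferroni-adjusted pairwise comparisons), and constrained PCoA
  (PCoA embedding + redundancy analysis on the erosion factor, reporting
  the fraction of inertia the gradient explains).
- **Co-occurrence networks**, one per site: OTUs with mean relative
  abundance > 0.01 %, all-pairs Spearman ρ with Benjamini–Hochberg
  q-values, correlation cutoff chosen by random-matrix theory (the
  threshold where the nearest-neighbour spacing distribution of the
  thresholded matrix's unfolded eigenvalues transitions from the
  Gaussian-orthogonal-ensemble law to Poisson e^(−d) statistics), and edges
  where |ρ| ≥ cutoff **and** q < 0.05. Global and per-sample
  (induced-subgraph) topology: node/edge numbers, mean betweenness, degree
  assortativity, transitivity.
- **Keystone OTUs:** degree > 6, weighted degree > 6, harmonic closeness
  > 0.14, betweenness centrality < 0.05, local clustering > 0.09.
- **Association layer:** OLS regressions (MF ~ diversity and network
  metrics), Pearson correlation matrices, Kruskal–Wallis with pairwise
  rank-sum letters, two-way ANOVA (site × erosion + transect block, Tukey
  post hoc), and redundancy analysis of taxon abundances on soil variables.
- **A synthetic-data generator** that emulates the two-site,
  4-erosion-level field design end-to-end (lognormal species-abundance
  distribution, correlated OTU guilds with hubs, erosion-linked declines,
  Table-style soil baselines) with ground truth, so the whole pipeline is
  testable without sequencing data.

## Worked example

```python
from edaphonet import (SimulationConfig, PipelineConfig,
                       generate_dataset, run_pipeline)

bundle = generate_dataset(SimulationConfig(seed=1))   # 48 samples, 2 sites
result = run_pipeline(PipelineConfig(seed=1), bundle.otu_table,
                      bundle.metadata, bundle.soil_table)

for name, site in result.sites.items():
    reg = site.regressions.set_index("predictor")
    print(f"{name}: threshold={site.threshold_used:.2f} "
          f"nodes={site.topology.node_number} edges={site.topology.edge_number} "
          f"keystones={int(site.keystones['keystone'].sum())}")
    print(f"  ANOSIM R={site.anosim.R:.3f} (p={site.anosim.p_value:.3f}); "
          f"CPCoA explained={100*site.cpcoa.proportion_explained:.1f}%")
    print(f"  MF ~ Shannon: slope={reg.at['shannon','slope']:.3f}, "
          f"r2={reg.at['shannon','r_squared']:.2f}, p={reg.at['shannon','p_value']:.2g}")
```

prints

```
loess: threshold=0.65 nodes=127 edges=893 keystones=64
  ANOSIM R=0.219 (p=0.005); CPCoA explained=16.4%
  MF ~ Shannon: slope=0.408, r2=0.46, p=0.00026
blacksoil: threshold=0.60 nodes=138 edges=1565 keystones=82
  ANOSIM R=0.173 (p=0.010); CPCoA explained=19.2%
  MF ~ Shannon: slope=0.723, r2=0.68, p=7.7e-07
```

Reading the output: at each site the RMT scan settled on a correlation
cutoff of ~0.6; community composition differs among erosion levels
(ANOSIM R > 0, small p), the erosion gradient explains 16–19 % of the
Bray–Curtis variation, and soil multifunctionality rises significantly
with Shannon diversity — the qualitative signature of erosion degrading
both the microbiome and soil function together.

The same pipeline runs from the shell:

```bash
edaphonet simulate --out-dir data --seed 1
edaphonet all --otu-table data/otu_table.tsv --metadata data/metadata.tsv \
              --soil data/soil.tsv --out-dir results_dir
```

Per-site outputs land in `results_dir/<site>/`: `diversity.tsv`,
`multifunctionality.tsv`, `network_edges.tsv` + `network.graphml`,
`rmt_scan.tsv`, `sample_topology.tsv`, `keystones.tsv`,
`regressions.tsv` and `summary.json`, plus a `pipeline.log` recording the
threshold grid and seeds. Individual stages are available as
`simulate`, `diversity`, `mf`, `network`, `keystones` and `associate`
subcommands.

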