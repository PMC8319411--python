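# Methods

This note documents the statistical procedures implemented in
`edaphonet`, the design choices behind them, and what the synthetic data
generator does and does not emulate.

## Study design assumed

The pipeline targets a replicated erosion-gradient design: two (or more)
sites, each with 2 transects/slopes × 4 erosion-intensity positions
(E0 non-eroded, EL light, EM moderate, EH heavy; erosion modulus classes
<500, 500–2500, 2500–5000 and 5000–8000 t km⁻² a⁻¹) × 3 plots, i.e. 24
composite samples per site. Sites are analysed separately by default (one
network, one MF scaling scope per site); a pooled mode exists but is off
because between-site baseline differences would dominate every statistic.

## Soil multifunctionality

Following the averaging approach common in the multifunctionality
literature, each of the 12 function variables is (i) tested for normality
with Shapiro–Wilk at α = 0.05; (ii) if rejected, transformed by whichever
of log or square root yields the larger Shapiro–Wilk p (ties go to log,
the more common choice for concentrations); variables containing values
≤ 0 (net N mineralization can be negative) are first shifted by
subtracting their minimum. Because the shifted minimum is exactly 0,
where log is undefined, the shifted log candidate uses log1p; (iii)
rescaled to [0, 1] by (x − min)/(max − min); (iv) averaged. pH is
excluded by default because it is already logarithmic. Conventions for
degenerate input: a constant variable is left untransformed and scaled to
0.5 everywhere (an uninformative midpoint keeps the 12-variable average
comparable) with a warning. Transform selection and scaling happen over
whatever set of plots is passed in — per site in the default pipeline —
and the choice is recorded per variable in the output.

## Diversity

Alpha diversity is computed on unfiltered counts (the network abundance
filter applies only to network construction) and without rarefaction;
read-depth heterogeneity is deliberately left visible (see the generator
section). Shannon uses natural logs. ACE uses the Chao–Lee form with
rare threshold 10; when every rare individual is a singleton the
coverage estimate C_ace is 0 and ACE is undefined, in which case the
bias-corrected Chao1 value is reported and flagged (`chao1_fallback`)
so the per-sample table stays complete.

ANOSIM uses Clarke's statistic on midranks of all n(n−1)/2 Bray–Curtis
dissimilarities with divisor n(n−1)/4, permutation p-value
(1 + #{R_perm ≥ R_obs})/(1 + n_perm), and Bonferroni-adjusted pairwise
two-group comparisons (both the global and pairwise p are reported). An
exact mode enumerates all distinct label assignments for small designs
and is used as the oracle in tests.

Constrained PCoA is implemented as classical metric PCoA of the distance
matrix (negative eigenvalues dropped rather than corrected — the simplest
defensible convention) followed by redundancy analysis of the embedded
coordinates on the constraint's indicator matrix. The explained
proportion is the between-group sum of squares over the total
positive-eigenvalue inertia, and significance is a permutation test of
the constraint labels (default 999 permutations; all permutation tests
take explicit seeds and are reproducible).

## Co-occurrence networks

OTUs with **mean per-sample relative abundance** strictly above 0.01 %
are retained (a pooled-counts variant is available by flag; the mean
convention is the package's choice where the field is split). Spearman ρ
uses midranks; two-sided p-values come from the t approximation with
n − 2 df; Benjamini–Hochberg q-values are computed over the upper
triangle. Pairs involving a constant OTU have undefined correlation,
are stored as NaN and can never become edges. Edges require
|ρ| ≥ threshold AND q < 0.05; negative correlations are admitted by
|ρ| (a positive-only flag covers the alternative reading).

### RMT threshold selection

The correlation cutoff is chosen by the random-matrix-theory transition:
thresholding a correlation matrix at increasing cutoffs moves its
nearest-neighbour eigenvalue spacing distribution from the
Gaussian-orthogonal-ensemble (GOE) law (level repulsion, characteristic
of a noise-dominated dense matrix) to Poisson e^(−d) statistics
(independent modules). For each grid threshold (default 0.30–0.99, step
0.01) the package zeroes sub-threshold entries, computes eigenvalues,
deduplicates exact degeneracies (zeroed blocks create large null
eigenspaces), trims spectral outliers beyond 3 × IQR (a handful of large
module eigenvalues otherwise distort the fit), unfolds the spectrum with
a cubic polynomial fit to the empirical cumulative spectral density, and
tests the mean-normalized spacings against the Poisson law and the
Wigner surmise by chi-square.

Numerical conventions chosen after explicit power analysis at the matrix
sizes this pipeline meets (tens to ~150 retained OTUs, i.e. only a few
dozen spacings): the chi-square uses **equal-probability bins** under the
tested law (5–10 bins so expected counts stay ≥ ~5), because fixed-width
fine binning leaves the test with ~60–80 % power to tell the two laws
apart at n ≈ 55 spacings, versus ~97 % with equal-probability cells. The
selected threshold is the smallest grid point at which the transition is
*complete* — Poisson accepted (p > 0.05) **and** GOE rejected
(p < 0.05) — sustained over ≥ 5 consecutive grid points. The sustained
run matters because neighbouring thresholds yield nearly identical
matrices: an isolated spurious acceptance in the dense regime would
otherwise propagate. The full scan (both p-values per threshold) is
logged so any selection can be audited, and a fallback threshold (default
0.70, configurable or disable-able) is used when no grid point qualifies.

### Topology and keystones

Global topology: node and edge numbers, mean normalized betweenness
(unweighted shortest paths, (n−1)(n−2)/2 normalization — the keystone
cutoff 0.05 only makes sense on the normalized scale), Newman degree
assortativity (undefined on degree-regular graphs and reported as NaN),
global transitivity (3 × triangles / connected triples), mean degree and
optional greedy-modularity score. Per-sample complexity induces the
subgraph on network OTUs with count > 0 in that sample and reports the
same metrics (empty induced subgraphs give missing rows).

Keystone OTUs satisfy all of: degree > 6, weighted degree (sum of |ρ|
over incident edges) > 6, closeness > 0.14, betweenness centrality
< 0.05 and local clustering coefficient > 0.09 (all strict). Closeness
is **harmonic** closeness normalized by n − 1, chosen because it is
defined on disconnected graphs, which thresholded co-occurrence networks
usually are; "transitivity" is interpreted as the node-local clustering
coefficient.

## Association layer

Regressions are ordinary least squares with the slope t-test (n − 2 df).
Kruskal–Wallis uses the midrank tie correction and a chi-square reference
with k − 1 df; the post hoc is pairwise two-sided Mann–Whitney tests with
Holm adjustment rendered as a compact letter display (insert-and-absorb).
A rank-based analogue of Duncan's multiple range test is not well
defined, so this replaces it deliberately. The site × erosion analysis is
a fixed-effects two-way ANOVA with the transect/slope entering as an
additive blocking factor (full random-effects REML estimation is out of
scope); the post hoc is Tukey HSD on erosion levels within site.
Redundancy analysis column-centers both matrices, projects the response
onto the explanatory column space via QR, reports
trace(fitted)/trace(total), and permutes rows for significance.
Per-taxon erosion effects are assessed by within-site Kruskal–Wallis
rather than a generalized linear mixed model, whose family/link for
relative abundances is not identifiable from the design alone.

## Synthetic data generator

The generator exists so every downstream stage can be validated against
known ground truth. It emulates:

- **Design:** 2 sites × 4 levels × 2 transects × 3 plots (24 samples per
  site) by default.
- **Soil:** per-site E0 baseline means and EH/E0 decline ratios for the
  13 variables patterned on published loess (sandy-loam) and black-soil
  (clay-loam) erosion gradients, interpolated geometrically across
  levels, with mean-preserving lognormal noise at coefficients of
  variation derived from the published standard errors. pH is held
  near-constant (erosion does not acidify on these gradients). Observed
  ratios slightly above 1 are clipped to 1 so the default gradient is a
  monotone decline; deliberately increasing variables requires an
  explicit opt-in flag.
- **Community:** a deterministic lognormal rank species-abundance
  distribution (σ = 1.0); erosion removes the rarest fraction of the
  background pool (up to `diversity_decline`, default 0.3, at EH) and
  steepens the distribution, so both richness and evenness decline.
  `n_blocks` guilds of `block_size` OTUs share a per-sample latent factor
  with within-guild correlation `block_rho` (default 0.8); hub OTUs load
  at √((1+ρ)/2) > √ρ so they carry the highest expected degree. Guild
  OTUs sit at a common moderate relative abundance (4 × 10⁻⁴) and decline
  `block_decline`-fold (default 8×) toward EH, which converts the
  abundance decline into presence/absence turnover and hence into the
  per-sample node- and edge-number declines the per-sample topology
  should detect. Counts are multinomial draws at lognormally varying
  depths (CV 0.35 around 20 000 reads), emulating uneven library sizes.
- **Truth:** guild memberships, hub identities, imposed per-level soil
  means and drawn depths are returned and serialized for validation.

The SAD spread (σ = 1.0) and latent log-abundance noise (σ = 0.6) were
chosen so per-sample Shannon variability matches field-scale amplicon
data of this richness rather than being dominated by single-OTU
blow-ups; with those values the imposed level-to-level differences are
resolvable at n = 6 plots per level per site, which is what the design
provides.

What it does **not** emulate: taxonomy (OTU identifiers are opaque),
phylogenetic structure, chimeras or read-level artifacts, spatial
autocorrelation along transects, and compositional closure effects
beyond the multinomial itself. Passing tests therefore demonstrate that
the statistical machinery recovers imposed effects of realistic size
under idealized sampling — not that any particular field result is
reproduced.

A separate utility builds block-structured correlation matrices directly
(signal blocks at |ρ| ≈ 0.9 over noise bounded by 0.4, part of the noise
mass sitting exactly at the bound so the random regime stays dense up to
it); these are used to verify that RMT threshold selection lands strictly
between the noise support and the signal blocks.

## Problem sizes and determinism

Default validation runs use 150 OTUs, 48 samples and ~20 000 reads per
sample; null-calibration checks use 200 replicates per test and
permutation tests at 99 permutations (the α = 0.05 rejection rule is
exact at that count). One global seed drives a hierarchical
seed-spawning scheme (separate streams for soil, community and each
stochastic test), so any table or p-value can be regenerated
independently and reruns are byte-identical.

## Known limitations

- The RMT spacing test needs ≥ 20 distinct eigenvalues; very small OTU
  sets must set the threshold manually.
- ACE is undefined when all rare taxa are singletons (flagged Chao1 is
  substituted); both estimators are depth-sensitive in the absence of
  rarefaction.
- The fixed keystone cutoffs (6 / 0.14 / 0.05 / 0.09) are
  convention, not inference; they are exposed in the configuration.
- CPCoA drops negative eigenvalues, slightly inflating the explained
  proportion for strongly non-Euclidean dissimilarities.
- The two-way ANOVA treats transects as fixed blocks; variance
  components attributable to transects are not estimated.
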