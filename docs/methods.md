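# Methods

`streamcom` implements the community-ecology inference chain of a
spatiotemporal amplicon survey of a freshwater river–lake network: ASV
count-table preprocessing, diversity statistics, phylogenetic null-model
partitioning of community assembly processes, distance-decay biogeography,
and abundance-occupancy core-microbiome detection. This note records the
models, the parameter choices that matter, and the design decisions taken
where the underlying methods literature leaves room.

## Preprocessing

Order of operations: taxonomy filter → global rarity filter → low-depth
sample filter → then either (A) rarefaction (diversity and null models) or
(B) cumulative sum scaling (distance-decay analysis).

- **Taxonomy filter.** A taxon is removed when any rank of its lineage
  equals one of the exclusion terms (default `Eukaryota`, `Mitochondria`,
  `Chloroplast`; exact, case-sensitive) or when its phylum rank is empty.
- **Rarity filter.** "Singletons and doubletons" are interpreted globally:
  taxa whose summed count across *all* samples is ≤ 2 (configurable) are
  removed. Per-sample removal would distort β-diversity, and the global
  convention is the common one for whole-table ASV filtering. The rule is
  defined on raw integer counts only.
- **Low-depth samples.** Samples below a configurable read threshold are
  dropped. The default of 1,000 reads is this package's choice — surveys of
  this kind exclude a handful of under-sequenced samples, but the exact
  cutoff is rarely published.
- **Rarefaction** subsamples each sample *without replacement*
  (multivariate hypergeometric, one draw per sample) to a common depth,
  default the smallest library size. The seed is explicit; a sample already
  at the target depth is returned unchanged. All-zero taxon columns that
  result are retained so matrix dimensions are stable.
- **CSS normalization.** For sample *j* the scaling factor `s_j` sums the
  counts of taxa whose nonzero count is ≤ the empirical q-th quantile
  (lower/type-1 convention, default q = 0.5) of the sample's nonzero
  counts; normalized values are `c_ij / s_j · median({s_j})`. The quantile
  is fixed rather than chosen adaptively per dataset: determinism is worth
  more here than the adaptive instability criterion of the original CSS
  formulation, which the analyses this package reproduces did not document
  using.

## Diversity

Chao1 uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, which is
defined even when no doubletons are observed. Shannon entropy is in nats
(no base is standard in the survey literature; nats makes Pielou evenness
exactly `H / ln S_obs`). Bray-Curtis is `Σ|a−b| / Σ(a+b)`. PCoA is
classical metric scaling: Gower double-centering of `−½D²`, symmetric
eigendecomposition, axes with non-positive eigenvalues dropped, proportions
computed over the positive spectrum only (no Lingoes/Cailliez correction —
the ordination is used for visualization-level summaries, not for distance
reconstruction). Environmental PCA z-scores the variables and decomposes
the correlation matrix; "PCA on a distance matrix of z-scored data" in the
source literature conflates two framings, and correlation-matrix PCA is the
interpretation implemented. `envfit` regresses each variable on the first
two axis scores; significance permutes the variable's values,
`p = (#{R²_perm ≥ R²_obs} + 1)/(n_perm + 1)`.

## Assembly null models

For a sample pair (A, B), the between-sample mean nearest taxon distance is

    βMNTD(A,B) = ½ [ Σ_{i∈A} f_iA · min_{j∈B} d(i,j)
                   + Σ_{j∈B} f_jB · min_{i∈A} d(j,i) ]

with `d` the patristic distance and `f` within-sample relative abundances
(abundance-weighted by default, since the chain runs on rarefied abundance
tables; presence-weighted `1/S` available by flag). Taxa present in both
samples contribute 0. βNTI standardizes the observed βMNTD against a
taxon-shuffle null — the taxon→tip mapping is permuted among all taxa of
the analyzed table (999 shuffles by default) — as
`(obs − mean_null)/sd_null`. βNTI is invariant to rescaling all branch
lengths. One set of shuffles is shared by all pairs of a run; marginally
each pair sees the same null distribution as with per-pair shuffles, at a
fraction of the cost. A pair whose membership is identical has a degenerate
null (every shuffle reproduces the observed value); the pipeline scores
such pairs βNTI = 0 with a logged warning, while the single-pair function
raises.

The abundance-based Raup-Crick index builds null pairs preserving each
sample's observed richness and library size: members are drawn without
replacement with probability proportional to occurrence frequency across
the table; each member receives one read and the remaining reads are
allocated multinomially with probability proportional to the members'
summed relative abundance across the table. RC compares observed
Bray-Curtis to the null with ties at half weight and is rescaled to
[−1, 1]. Ties are counted at half weight to avoid bias at coarse null
resolution.

Classification (thresholds ±2 for βNTI, ±0.95 for RC):

| condition                   | process                |
|-----------------------------|------------------------|
| βNTI < −2                   | homogeneous selection  |
| βNTI > +2                   | variable selection     |
| \|βNTI\| ≤ 2, RC > +0.95    | dispersal limitation   |
| \|βNTI\| ≤ 2, RC < −0.95    | homogenizing dispersal |
| otherwise                   | undominated            |

The pair universe for partitioning is all within-group pairs (default
group: season), matching the per-season framing of such analyses.

## Biogeography and core detection

Geodesic distances are computed on the WGS-84 ellipsoid with Vincenty's
inverse method (λ-iteration to 1e-12; nearly antipodal non-convergence
raises). Distances are in meters and the distance-decay slope is reported
per meter. The DDR is an OLS fit of `1 − Bray-Curtis` (on CSS-normalized
abundances) against geodesic distance, optionally restricted to a subset of
samples (e.g. the longest-flow tributary plus downstream sites) with a
second all-samples fit.

Core membership requires occupancy exactly 1 — detection in every analyzed
sample, pooled across seasons by default. The abundance axis is log10 of
the zero-inclusive mean relative abundance (log of mean, not mean of log).
Stream-type sharing classes are computed independently of the core
criterion: detected in one stream type → `unique_<type>`, two →
`shared_two`, all three without full occupancy → `shared_three` (this
fifth class keeps the classification exhaustive; taxa present in all three
types are not automatically core). `core_coverage` averages, per stream
type, the summed relative abundance of core taxa. `venn_partition` counts
taxa in the seven regions of the three-group presence partition.

## Statistics

One-factor PERMANOVA with sums of squares from squared distances
(`SS_total = Σ_{i<j} d²/n`, within-group analogue per group), pseudo-F
`(SS_b/df_b)/(SS_w/df_w)`, and label-permutation p-values with the +1
correction (default 999 permutations; never exactly 0). On Euclidean
distances the pseudo-F equals the classical one-way statistic, which the
tests assert. ANOVA, Tukey's HSD (Tukey-Kramer for unbalanced designs) and
Pearson correlation delegate to scipy.

## Synthetic worlds

The generator emulates the survey's shape — 25 sites in three stream-type
groups (18 tributary, 6 interlake, 1 terminal outflow) on a ≤ 20 km line
network, up to six seasonal campaigns, libraries uniform in
[1,000, 18,000] reads — and plants a known assembly regime so each pipeline
stage has ground truth. Sampling weight of taxon *i* in sample *s*:

    w_is ∝ m_i · B_is · f(niche_i, env_s) · exp(−|x_i − x_s|/δ)

- `m_i`: regional log-normal abundance (σ = 1.0).
- `B_is`: colonization lottery. Propagule arrival is Poisson with mean
  `rate · m_i / m̄` (rate 1.0), so establishment failure is
  `exp(−rate · m_i/m̄)`: regionally abundant taxa essentially always
  arrive, rare taxa colonize stochastically. This yields a realistic
  abundance-occupancy relationship and supplies the membership turnover
  among ecologically equivalent taxa that selection regimes act on. An
  earlier design used an abundance-independent lottery; it occasionally
  removed a highly abundant, phylogenetically isolated taxon from single
  samples, which dominates the abundance-weighted βMNTD of those pairs and
  produces spurious overdispersion — a behavior of the weighted statistic
  worth knowing about, but not a useful property for a calibration
  baseline.
- `f`: the selection kernel. Under `gradient_filtering` it is a Gaussian,
  width σ_f = 0.5 SD, on a Brownian-motion trait (root value 0, increments
  `N(0, rate·branch)`) around an environmental optimum running from −2 to
  +2 trait SD along the network. Under `homogeneous_filtering` all sites
  share one environment favoring a *perfectly phylogenetically conserved*
  niche: a Gaussian kernel on patristic distance to the tree's most compact
  20–40-tip clade (scale 0.1 tree heights, i.e. effectively the clade).
  The clade-level niche is deliberate: at a 150-taxon pool, a Gaussian band
  on a Brownian trait selects a phylogenetically loose set (Brownian
  lineages repeatedly cross any trait value), and the homogeneous-selection
  signature — communities more related than the taxon shuffle expects — is
  then too weak for nearest-taxon statistics to detect at all. Perfect
  conservatism is the limiting case of the same model and plants a
  detectable signature at desk scale.
- dispersal kernel: exponential with e-folding scale δ = 1,500 m from each
  taxon's home position, used by `dispersal_limited` and `mixed`.

Trees are pure-birth (Yule) with all tips extant, hence ultrametric;
extinction adds parameters without adding anything the statistics being
validated would detect. Environmental metadata columns carry season-typical
means (temperature, O₂, DOC, Ca²⁺, NO₃⁻, rainfall); under gradient regimes
the nitrate column carries the planted spatial gradient (r ≥ 0.9 with
position by construction).

What the generator does *not* emulate: sequencing error and chimeras,
compositional biases of PCR, taxon-specific detection efficiency, within-
season temporal autocorrelation, or hydrologic (along-network) rather than
Euclidean dispersal paths. Passing recovery tests therefore shows the
inference chain correctly identifies planted regimes under multinomial
sampling — not that real freshwater data satisfy these models.

## Problem sizes and numerics

Recovery checks run at 150 taxa × 12 sites × 199 null draws per test
(seconds to ~1 minute each); self-calibrations use 100–200 pairs with
999 and 199 null draws respectively; PERMANOVA calibration uses 500
simulations × 199 permutations. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands. All Monte-Carlo procedures
take explicit integer seeds; reruns are bit-identical. Vincenty iterations
converge to 1e-12 radians (sub-millimeter); agreement with an independent
high-precision geodesic reference is ≤ 1e-4 m on test pairs. Floating-point
ties in the Raup-Crick comparison use a 1e-12 tolerance.

## Known limitations

- The taxa-shuffle βNTI null conditions on the analyzed table's taxon pool;
  if the pool itself is strongly filtered (every sample from the same
  narrow habitat), homogeneous selection is intrinsically hard to detect —
  a property of the method, reproduced faithfully here.
- One-factor PERMANOVA only; no PERMDISP companion test, so location and
  dispersion effects are confounded as in the original analyses.
- The distance-decay regression treats pairs as independent observations
  (as is conventional); its p-value is anti-conservative under the pair
  dependence structure, which the planted-recovery test sidesteps by
  checking sign and recovery rather than calibrated coverage.
- Raup-Crick self-calibration holds when the procedure's estimated
  occurrence/abundance profiles match the generating ones; with few samples
  the estimates are noisy and RC acquires a small positive bias.
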