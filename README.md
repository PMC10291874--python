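# streamcom

Community-assembly inference for freshwater-network microbiomes.

Interconnected river–lake systems ("freshwater networks") carry microbial
communities that are shaped partly by the environment at each site
(selection / species sorting) and partly by who happens to arrive there
(dispersal and drift / mass effects). `streamcom` implements, as a tested
and reusable pipeline, the analysis chain used to disentangle these forces
from amplicon survey data: ASV count tables, a phylogeny of the ASVs,
sample metadata with coordinates and environmental measurements. It is
written for microbial ecologists who want the full chain — preprocessing
through process partitioning — reproducible from one config file, and
verifiable against synthetic data with known ground truth.

## What it computes

**Preprocessing** — organelle/eukaryote and phylum-unassigned taxon
removal, global singleton/doubleton filtering, low-depth sample exclusion,
rarefaction to the smallest library (without replacement), and cumulative
sum scaling (CSS) normalization.

**Diversity** — Chao1 (bias-corrected), Shannon (nats), Pielou evenness;
Bray-Curtis dissimilarity; PCoA; PCA of z-scored environmental variables;
`envfit`-style vector fitting; one-factor PERMANOVA, ANOVA + Tukey HSD,
Pearson correlation.

**Assembly null models** (the core) — for every within-group sample pair:

- βMNTD, the abundance-weighted mean nearest-taxon patristic distance
  between two communities;
- βNTI = (βMNTD_obs − mean_null) / sd_null against a taxon–tip shuffle
  null (999 draws);
- abundance-based Raup-Crick (RC_bray) against null communities that
  preserve each sample's richness and library size;
- a five-way process classification: βNTI < −2 homogeneous selection,
  βNTI > +2 variable selection, otherwise RC > +0.95 dispersal limitation,
  RC < −0.95 homogenizing dispersal, else undominated — aggregated into
  per-group process fractions.

**Biogeography & core** — Vincenty (WGS-84 ellipsoid) geodesic distances;
distance-decay regression of CSS Bray-Curtis similarity on distance;
abundance-occupancy core-microbiome detection (core = occupancy 1);
per-stream-type core coverage; three-way Venn partition of shared and
unique taxa.

**Synthetic worlds** — a generator that emulates the survey design
(~25 sites in three stream types, six seasons, libraries of 1,000–18,000
reads) and plants known assembly regimes (`neutral`,
`homogeneous_filtering`, `gradient_filtering`, `dispersal_limited`,
`mixed`), so every stage of the chain can be validated against ground
truth. See `docs/methods.md` for the model.

## Worked example

Generate a world in which every site filters for the same phylogenetically
conserved niche (planted homogeneous selection), then run the null models:

```bash
streamcom simulate --outdir demo --regime homogeneous_filtering \
    --n-taxa 150 --n-sites 12 --n-seasons 1 --seed 4
streamcom assembly --counts demo/counts.tsv --tree demo/tree.nwk \
    --metadata demo/metadata.tsv --outdir demo/out --n-null 199 --seed 4
```

which prints the per-group process fractions:

```
        homogeneous_selection  variable_selection  dispersal_limitation  homogenizing_dispersal  undominated
group
spring               0.984848                 0.0                   0.0                     0.0     0.015152
```

98.5% of the 66 within-season sample pairs are classified as homogeneous
selection (βNTI < −2): communities are more phylogenetically similar than
the taxon-shuffle null expects, exactly the planted signal. The remaining
1.5% fall in the undominated class. For comparison, the distance-decay
regression on the same (selection-dominated, dispersal-unlimited) world

```bash
streamcom biogeo --counts demo/counts.tsv --metadata demo/metadata.tsv --outdir demo/out
# DDR slope=-1.283e-05 per m, R^2=0.058, n=66
```

shows only a weak, noisy decay — distance explains ~6% of similarity
variance here, as it should when selection rather than dispersal structures
the metacommunity.

The same stages are available as library functions
(`streamcom.assembly.assembly_pipeline`, `streamcom.biogeo.ddr`, …), and
`streamcom run --config config.yaml` executes the whole chain
(preprocess → diversity → assembly → biogeography/core) with every seed
recorded, writing TSV outputs plus a JSON run report that makes reruns
bit-identical.

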