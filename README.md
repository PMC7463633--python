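# fusemet

Differential-abundance and fused-network pathway-enrichment analysis for
two-group cell-line metabolomics/lipidomics studies, with a Chou–Talalay
combination-index module for drug-interaction screens.

The package re-implements, as a tested and reusable pipeline, the
computational analysis of a study of dedifferentiated liposarcoma (DDLPS)
cell lines stratified by *MDM2* amplification: metabolite/lipid feature
tables from six patient-derived lines in two MDM2 groups are preprocessed,
tested for differential abundance with a linear mixed model, and the
resulting hit list is interpreted with a network-based pathway enrichment
that fuses pathway co-membership with chemical structure similarity.  Every
stage is exercisable on synthetic studies with planted ground truth, so the
pipeline's operating characteristics (sensitivity, false-discovery control,
pathway recovery, permutation-null calibration) are measurable without any
external download.

## Methods at a glance

**Preprocessing** (`fusemet.feature_io`) — features missing in ≥ 50% of
samples are removed; abundances are normalized per sample (protein
concentration) and median-scaled per feature; features whose
within-replicate-group coefficient of variation, CV = 100·σ/μ, exceeds 150
are removed as technical artifacts; remaining missing values are imputed to
the feature minimum and abundances are log2-transformed.  Lipidomic tables
are TIC-normalized per ionization mode and merged across modes (MS2
identifications only; highest-abundance duplicate kept; negative adducts
preferred; sodium adducts used only as a last resort).

**Differential abundance** (`fusemet.differential`) — per feature,

```
y = β₀ + β₁·group + u_cellline + ε,   u ~ N(0, σᵤ²),  ε ~ N(0, σ²)
```

fitted by REML with the cell line of origin as a random intercept; log2FC =
β̂₁ with a Wald test, Benjamini–Hochberg FDR correction, and the selection
rule q < 0.05 and |log2FC| > 0.75.

**Network enrichment** (`fusemet.network_enrichment`) — significant
metabolites that map to the pathway database seed the analysis; the universe
is every metabolite of every seed-containing pathway.  Two networks are
built over the universe: edge weights J(u,v) = |Aᵤ∩Aᵥ|/|Aᵤ∪Aᵥ| on pathway
annotation sets, and a chemical-similarity layer with weight-1 edges for
fingerprint pairs at or above the 90th percentile of Tanimoto similarity
T = c/(a+b−c).  The layers are fused by summing edge weights; random walk
with restarts, p ← (1−r)·W·p + r·e (restart r = 0.7), scores proximity to
the seeds; each node's score is referred to its distribution over 10,000
random seed sets of the same size, nodes at the ≥ 97th percentile join the
seeds in a subnetwork; Louvain communities of that subnetwork are tested for
pathway over-representation (one-sided hypergeometric, BH q < 0.05).

**Combination index** (`fusemet.drug_combination`) — the median-effect
equation fa/(1−fa) = (D/Dm)^m is fitted by linear regression of logit(fa) on
log D, and two-drug interaction is quantified by the Chou–Talalay index
CI = d₁/Dx₁ + d₂/Dx₂ with Dxᵢ = Dmᵢ·(fa/(1−fa))^(1/mᵢ); CI > 1 indicates
antagonism.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a synthetic
study whose shape mirrors the emulated experiment (541 features before
filtering, 6 cell lines × 3 replicates, 17 planted |log2FC| = 1.5 effects,
33 planted heavily-missing and 28 planted high-CV features):

```sh
python analysis/01_simulate_study.py
python analysis/02_preprocess.py
python analysis/03_differential_abundance.py
python analysis/04_network_enrichment.py
python analysis/05_combination_index.py
python analysis/06_benchmarks.py
```

which prints, stage by stage:

```
read 541 features; removed 33 by missingness and 28 by CV; 480 remain
18 features selected (11 up, 7 down); 17/17 planted effects recovered
10/18 candidates mapped; universe 52 metabolites; subnetwork 10 nodes
  cluster 0: PW00_planted (planted module) overlap 8/13, q=1.03e-05
doxorubicin_like: m=1.284, Dm=0.630 uM, R2=0.9999
20/20 dose pairs have CI > 1 (antagonism), consistent with the emulated combination
```

Reading: all but one of the 18 selected features are planted effects; of the
18 candidates, the 10 that carry pathway annotations seed the network stage;
the planted pathway module is recovered as an enriched cluster at
q ≈ 1×10⁻⁵; and the simulated antagonistic drug pair yields combination
indices above 1 across the dose grid.  `analysis/06_benchmarks.py` then
reports sensitivity ≈ 0.98 and empirical FDR ≈ 0.046 over 50 studies, 20/20
planted-pathway recoveries, and a uniform self-null percentile distribution
(KS p ≈ 0.26, 3.1% of nodes at or above the 97th percentile).

The same pipeline is available as a CLI (`fusemet simulate|preprocess|
differential|enrich|combo|run-all`) for use on real feature tables; inputs
are plain TSV/GMT files (see `fusemet.feature_io` and
`fusemet.network_enrichment` docstrings for the formats).

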