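# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `fusemet` pipeline.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being modelled

The pipeline targets comparative metabolomics/lipidomics of cultured cell
lines: a small number of patient-derived lines (here six) split into two
biological groups (higher vs lower *MDM2* amplification, or treated vs
untreated), each profiled in ≥ 3 replicates.  The unit of biological
replication is the cell line; replicates of the same line are technical or
near-technical repeats.  This hierarchy drives both the statistical model
(cell line as a random intercept) and the synthetic-data generator.

## Preprocessing

Order of operations: missingness filter → sample normalization and
per-feature median scaling → CV filter → minimum imputation → log2.

* **Missingness filter.** A feature is removed when its missing fraction is
  ≥ `max_missing_frac` (default 0.5, boundary inclusive).  Missing entries
  are tracked in an explicit mask and never silently zero-filled.
* **Normalization.** Each sample column is divided by its
  `normalization_factor` (e.g. Bradford protein concentration; the step is
  skipped with a warning when factors are absent), then each feature is
  rescaled so its across-sample median of observed values is 1.  Median
  scaling is per feature and therefore cancels in any within-feature group
  contrast; it only fixes the display scale.
* **CV filter.** CV = 100·sd/mean is computed on normalized (pre-log)
  values within each replicate group (same cell line × treatment), over
  observed values only (imputing first would bias the CV downward).  A
  feature is removed when its maximum group CV strictly exceeds
  `cv_threshold` (default 150).  A group with mean 0 (no signal) counts as
  infinite CV; groups with < 2 observed values are skipped.  Replicate-level
  CV is used because extreme within-replicate variability indicates
  technical error rather than biology.
* **Imputation.** Remaining missing entries are set to the feature's
  observed minimum, the convention of the emulated platform; the missing
  mask is preserved as provenance.  *Limitation:* under left-censored
  missingness, minimum imputation concentrates identical low values in
  whichever cell lines happen to sit lowest, and this can manufacture
  spurious group differences (observed in simulation as extra false
  positives at a rate well under one feature per 480-feature study at 5%
  missingness).  Analyses sensitive to this should drop heavily-missing
  features more aggressively rather than trust imputed contrasts.
* **Lipidomic specifics.** Positive- and negative-mode tables are
  TIC-normalized independently (each column divided by its total ion
  current and rescaled by the mode's median TIC, so within-mode column sums
  are equal while magnitudes remain interpretable; the rescaling constant
  is irrelevant downstream because all inference is on log2 differences),
  log2-transformed, and merged: only MS2-confirmed identifications are
  kept; within a mode, sodium adducts are set aside whenever a non-sodium
  adduct reports the same lipid, and duplicate identifications collapse to
  the highest mean abundance; identifications present in both modes keep
  the negative-mode row; sodium adducts survive only when no other adduct
  reports the lipid.  Each merged row records its source feature and mode.

## Differential abundance

Per feature, the linear mixed model

y_ij = β₀ + β₁·group_i + u_i + ε_ij, u_i ~ N(0, σᵤ²), ε_ij ~ N(0, σ²),

is fitted by REML, with i indexing cell lines.  β̂₁ is the log2 fold change
(comparison − reference; equal to the difference of group means of cell-line
means in balanced designs) and the Wald statistic β̂₁/se(β̂₁) referred to the
standard normal gives the p-value.

* **Balanced fast path.** With equal replicates per line, group constant
  within line and no missing values, the REML estimates have the classical
  closed form via the within-line mean square (MSW) and the between-line,
  within-group mean square (MSB): σ̂² = MSW, σ̂ᵤ² = (MSB − MSW)/r, and
  var(β̂₁) = (σ̂ᵤ² + σ̂²/r)(1/L₁ + 1/L₂) = MSB/r · (1/L₁ + 1/L₂).  This is
  vectorized across features (a 480-feature study fits in milliseconds) and
  is asserted against `statsmodels` MixedLM in the unit tests.  Unbalanced
  or incomplete data fall back to a per-feature MixedLM fit.
* **Degenerate fits.** When σ̂ᵤ² ≤ 0 (or a MixedLM fit fails), the feature
  is refitted by ordinary least squares and marked `fallback_fixed`.
  Constant features get p = 1 and a flagged standard error.
* **Small-sample behaviour.** With six cell lines the effective degrees of
  freedom for the group contrast are small, and the Wald z reference is
  liberal at the raw 0.05 level (the simulated null rate is ≈ 0.10–0.12
  rather than 0.05).  The pipeline's *selection* rule — BH q < 0.05 **and**
  |log2FC| > 0.75 — restores error control in practice because a false
  positive must also show a large estimated effect; the acceptance suite
  measures the resulting empirical FDR directly.  A t reference with
  between-within degrees of freedom would be more conservative per test but
  has essentially no power at BH-adjusted thresholds in this design; the
  Wald choice is deliberate and recorded in the output metadata.
* **Multiple testing.** Benjamini–Hochberg step-up within each analysis
  panel (metabolomic or lipidomic), via `statsmodels`, verified against an
  independent step-up implementation.

## Network-based pathway enrichment

1. **Seeds and universe.** Candidates (the selected differential
   metabolites) that carry pathway annotations become seeds; the universe
   is the union of member sets of every seed-containing pathway.  The
   enrichment background is this universe (the full-database background is
   available by flag); the rationale is that the walk can only ever visit
   universe members, so the universe is the fair sampling frame.
2. **Pathway layer.** For every universe pair, the edge weight is the
   Jaccard index of their pathway annotation sets; zero-Jaccard pairs are
   absent edges (the graph stays sparse).
3. **Chemical layer.** Tanimoto similarity is computed for all unordered
   pairs of fingerprinted universe members; the binarization threshold is
   the 90th percentile of that distribution over **all** pairs (including
   zeros; a nonzero-only option exists), boundary inclusive; qualifying
   pairs get weight 1, everything else no edge; members without
   fingerprints stay isolated in this layer.
4. **Fusion.** Edge weights are summed across layers (pathway weights in
   (0,1], chemical weights exactly 1, fused weights in (0,2]).
5. **Propagation.** Random walk with restarts, p ← (1−r)W p + r e, with W
   the column-stochastic adjacency (each column divided by its weighted
   degree), e uniform over the seeds, restart probability r = 0.7 (standard
   in the network-propagation literature; configurable and echoed in the
   run report), L1 convergence tolerance 1e-10, max 10,000 iterations.
   Columns of isolated nodes redistribute their mass to the seed vector,
   keeping the chain stochastic; scores sum to 1.
6. **Permutation null.** The same propagation is run for `n_perm` (default
   10,000) random seed sets of the observed mapped-seed size, drawn
   uniformly without replacement from all network nodes (an option excludes
   the true seeds).  Because the stationary solution is linear in the seed
   vector, the fundamental matrix K = r(I − (1−r)W)⁻¹ is inverted once and
   each permutation costs only a column average — 10,000 permutations on a
   few-hundred-node network take seconds.  Each node's percentile is the
   midrank position (ties counted half) of its observed score in its own
   null distribution; per-node rather than pooled nulls control for degree
   and position effects.
7. **Subnetwork, clusters, enrichment.** Nodes at percentile ≥ 97
   (inclusive) join the seeds in the induced subnetwork; Louvain
   modularity communities (seeded, deterministic) are each tested for
   pathway over-representation with the one-sided hypergeometric test
   against the annotated universe, BH-corrected jointly across all
   cluster × pathway tests (per-cluster correction available), flagged at
   q < 0.05.

## Combination index

The median-effect line log₁₀(fa/(1−fa)) = m·log₁₀ D − m·log₁₀ Dm is fitted
by least squares (base 10; any base is self-consistent).  Fractions affected
of exactly 0 or 1 are rejected, not clipped — the logit is undefined there
and silent clipping biases the slope.  The two-drug combination index uses
the mutually exclusive form CI = d₁/Dx₁ + d₂/Dx₂; classification uses a
configurable additivity band δ = 0.1 (synergy below 1−δ, antagonism above
1+δ).

## Synthetic data and what the benchmarks do (and do not) show

The generator produces log2 abundances y = μ_f + β_f·group + u_line + ε with
u ~ N(0, 0.25²) and ε ~ N(0, 0.30²) by default (≈19% cell-line and ≈23%
replicate coefficients of variation on the natural scale — values chosen
once as representative of well-run cell-line metabolomics), β_f = ±1.5 for
17 of 480 features, exponentiated to raw scale and multiplied by per-sample
protein factors U(0.8, 1.2).  Left-censored missingness (5% by default,
rank-weighted within feature; an MCAR option exists), 33 heavily-missing
features (50–80% missing) and 28 high-CV features (one 500–1500× spike per
replicate group) complete the 541-feature pre-filter table.  The pathway
generator creates 20 pathways of 8–15 members with 20% of each pathway's
membership drawn from previously used metabolites (multi-membership, as in
curated databases) and one planted module; fingerprints inherit a
per-pathway template with 10% bit flips, so within-pathway Tanimoto
similarity is elevated.

These simulations share the real data's *structure* (hierarchy, effect
scale, censoring, annotation overlap) but not its biology: effects are
independent across features, noise is Gaussian on the log scale, annotation
sets are small and regular, and fingerprints are caricatures of real
chemistry.  Passing benchmarks therefore demonstrate the *correctness and
calibration of the algorithms* under the stated model — not that any
particular biological conclusion transfers.

Benchmark problem sizes (50 studies for the differential benchmark, 20 runs
at 2,000 permutations for pathway recovery, 480 independent self-null
experiments at 2,000 permutations) were chosen to give stable Monte-Carlo
estimates in seconds-to-minutes on one CPU.  For the self-null calibration,
one node is sampled per independent experiment because percentiles of
different nodes within one experiment are correlated (they share a single
observed seed draw and the graph topology); the subsample is exactly iid,
making the Kolmogorov–Smirnov test and the binomial tail band valid.  The
exchangeable expectation of P(percentile ≥ 97) at n_perm = 2,000 with
midrank ties is 61/2001 ≈ 3.05%, which is the reference value the checks
use.

## Determinism

All stochastic stages draw sub-seeds from a single top-level seed via
`numpy` seed sequences; Louvain receives an explicit seed; every writer
emits fixed float formats and deterministic row/column order.  Two runs with
the same configuration and seed produce byte-identical result tables.

## Known limitations

* The Wald z reference is liberal per test in very small designs (see
  above); per-test calibrated inference would need Satterthwaite or
  Kenward–Roger degrees of freedom.
* Minimum imputation can fabricate group differences under left-censoring;
  the missingness filter bounds, but does not eliminate, this artifact.
* The enrichment background is the seed universe; pathways wholly outside
  the universe are untestable by construction.
* The percentile-based subnetwork extraction keys on the *null* of random
  seed placement; a node can be "proximal" merely by sitting between two
  seed clusters.
* Chemical-layer binarization discards similarity magnitude above the
  threshold; alternative weightings are not explored.
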