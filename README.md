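# acclimkit

Analysis toolkit for short-term thermal-acclimation experiments in
reef-building corals (and similar factorial stress designs): from a raw
gene × sample count matrix and a treatment/day/condition design table to
acclimation-associated co-expression clusters, resampling-null tests of
their heat-stress response, quantification of *transcriptional
dampening* versus *frontloading*, and a chlorophyll-a bleaching
phenotype analysis.

## The problem

Corals acclimated for days to elevated or fluctuating temperature bleach
less under acute heat stress. The transcriptomic signature of this rapid
acclimation is not a change in baseline expression but a **muted stress
response**: genes that respond strongly to acute heat in
control-acclimated colonies respond less in heat-acclimated ones.
`acclimkit` implements the full analysis that establishes this pattern:

1. **Filtering & normalization.** Keep contigs with mean count > 5 and
   sample SD < mean; normalize by median-of-ratios size factors
   `s_j = median_g count[g,j] / (∏_k count[g,k])^{1/n}`.
2. **QC.** PCA of log-expression over samples; robust z-scores
   `|score − median| / (1.4826·MAD)` on PC1/PC2 flag artifact samples.
3. **Per-gene permutational ANOVA** `y ~ treatment + day` (Type-II sums
   of squares, response permuted against the fixed design), run
   separately for stressed and nonstressed branches, with
   Benjamini–Hochberg FDR; acclimation-associated genes are those with
   q(treatment) ≤ 0.01.
4. **Co-expression clusters.** Average-linkage hierarchical clustering
   on 1 − Spearman ρ, tree cut at ρ > 0.6; each cluster is summarized by
   its **eigengene** (centered first principal component of the
   standardized member profiles) and tested by a permutational
   treatment × day ANOVA.
5. **Heat-stress response.** Per gene,
   `log2FC = log2((mean stressed + 1) / (mean nonstressed + 1))`; a
   cluster's mean response is compared against 1,000 randomly resampled
   same-size gene sets (empirical two-sided p, 95% envelope).
6. **Dampening & frontloading.** Through-origin regression of acclimated
   on control per-gene responses — slope < 1 with a bootstrap CI
   excluding 1 means dampening; genes are labeled `dampening`
   (muted response, unchanged baseline), `frontloading` (baseline
   already shifted before stress), or `none`.
7. **Bleaching phenotype.** Chlorophyll a from four-wavelength
   absorbance (quadrachromatic equation for 95% ethanol), branch surface
   area from wax-dip weight gain calibrated against standards, and the
   retained chlorophyll fraction (stressed/nonstressed density per
   colony) tested by permutational ANOVA with day 0 excluded.

A synthetic-data module generates the full 144-sample design
(3 acclimation regimes × 6 colonies per batch × 4 days ×
stressed/nonstressed branches), negative-binomial counts with planted
co-expression modules, treatment-dependent dampening, size factors, a
nine-sample tank artifact, and phenotype records with known ground
truth — so every stage of the pipeline is testable end to end without
any external data.

## Worked example

Run the whole pipeline on a synthetic experiment (the `--permutations
4999` raises p-value resolution so BH-FDR at 0.01 can rank discoveries
among ~1,800 genes):

```sh
$ acclimkit all --simulate --seed 1 --out-dir run1 --permutations 4999
done: 1722 genes analysed, 121 acclimation-significant (stressed), 2 clusters
```

`run1/summary.json` then contains (seed 1):

```
n_genes_filtered            1722   # of 2000 simulated contigs pass mean>5, SD<mean
n_outliers_flagged             9   # the planted artifact tank, exactly recovered
n_significant_stressed       121   # acclimation-associated genes after heat stress
n_significant_nonstressed     47   # the planted frontloaded baseline-shift genes
cluster_sizes           {cluster_1: 40, cluster_2: 10}
cluster_null_p          {cluster_1: 0.000999, cluster_2: 0.0150}
dampening_slope         {stable31: 0.384, variable29_33: 0.388}
n_stable_vs_variable_stressed  0   # identical acclimated regimes: no discoveries
phenotype_anova         p_treatment = 0.0002
```

Reading these numbers: the QC stage flags exactly the nine artifact
samples; the stressed-branch ANOVA recovers planted
acclimation-modulated genes and clusters them; cluster 1's mean stress
response falls far outside the resampled null envelope (p ≈ 0.001); the
through-origin slope of acclimated on control responses is ≈ 0.39 —
recovering the planted dampening factor d = 0.4, i.e. acclimated
colonies mount ~40% of the control transcriptional response; the
stable-vs-variable contrast finds nothing (the two acclimated regimes
are generated identically); and the bleaching phenotype shows a strong
acclimation effect on retained chlorophyll.

Every stage is also available as a library function
(`acclimkit.permutation_pvalues`, `acclimkit.build_cluster_set`,
`acclimkit.cluster_null_test`, `acclimkit.dampening_index`, ...) and as
individual subcommands (`simulate`, `normalize`, `qc`, `anova`,
`cluster`, `respond`, `phenotype`).

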