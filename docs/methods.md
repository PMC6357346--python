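# Methods

## Overview

`fuzzsig` implements an integrative strategy for selecting tumor/normal gene
signatures from paired expression and promoter-methylation data, and a
Mamdani fuzzy-rule classifier built on the selected genes. The pipeline has
four stages:

1. **Differential calling.** Genes are tested for differential expression on
   the log2 scale (Welch two-sample t-test per gene); a gene is a DEG when
   |mean log2 difference| > 1 (i.e. two-fold) and the BH-adjusted p-value is
   below 0.01. CpG loci are tested the same way on beta values; a locus is a
   DML when the adjusted p < 0.01 and |Δβ| > 0.1. Gene-level methylation
   status (DMG) combines the **raw** p-values of all CpGs in the promoter
   window (TSS−1500 to TSS+500, reflected on the − strand) with Fisher's
   method, −2·Σ ln pᵢ ~ χ²(2k); BH q-values are computed across the genes
   whose promoter contains at least one DML, and a gene is a DMG when it has
   ≥ 1 DML and q < 0.01.
2. **Candidate intersection.** Candidates are genes simultaneously DEG and
   DMG — the joint requirement filters expression hits whose methylation
   state does not corroborate them, and vice versa.
3. **Biomarker-weighted elastic net.** A binomial elastic-net model
   (α = 0.5 by default) is fitted over the candidates plus the reported
   biomarker panel. Panel genes receive a per-feature penalty multiplier
   (default 0.1; 0 means effectively unpenalized, i.e. forced retention).
   λ is chosen by seeded stratified internal CV minimizing deviance; genes
   with nonzero coefficients at the chosen λ form the signature.
4. **Fuzzy classification.** Each signature gene is min–max normalized to
   [0, 1] on training data and covered by three Gaussian linguistic terms —
   small, medium, large at centers 0, 0.5, 1 with σ = 0.175. Rules are
   induced by the Wang–Mendel construction and evaluated with min/max
   Mamdani inference; the signed aggregate difference serves as a continuous
   score for ROC analysis.

## Parameters that matter

| parameter | default | units / scale | notes |
|---|---|---|---|
| DEG log2-FC threshold | 1 | log2 | two-fold change; configurable |
| DEG/DML adjusted-p threshold | 0.01 | — | BH by default; Bonferroni available |
| DML Δβ threshold | 0.1 | beta | effect-size gate on top of significance |
| promoter window | −1500/+500 | bp around TSS | strand-reflected; strand-agnostic mode available |
| DMG q threshold | 0.01 | — | no published cutoff exists; mirrors the DEG/DML stringency |
| elastic-net α | 0.5 | — | L1/L2 mixing |
| biomarker penalty multiplier | 0.1 | — | 1 = ordinary gene, 0 = forced in |
| λ rule | min CV deviance | — | 1-SE rule available (`lambda_rule="1se"`) |
| fuzzy σ | 0.175 | normalized expression | per the published membership functions |
| CV folds | 10 outer / 5 inner | — | stratified, seeded |

## Design decisions

* **Welch vs pooled t-test.** The t-test is Welch's (unequal variance) in
  both data types — the robust default for the unequal tumor/normal group
  sizes typical of public cohorts.
* **Fisher combination over all promoter loci.** The combined statistic uses
  every promoter CpG's raw p-value, not only the flagged ones, so one
  inaccurate locus (e.g. from a computational methylation-expansion step with
  ~90% per-locus accuracy) cannot flip a promoter's status by itself; the
  ≥ 1-DML requirement is a separate gate. `combine="dml_only"` restricts the
  pool to flagged loci. Zero p-values are clamped to 1e−300 before the log.
* **Penalty weighting by column scaling.** Per-feature penalty multipliers
  w_j are realized by dividing (standardized) column j by w_j before an
  unweighted fit and rescaling the coefficient afterwards. This puts w_j on
  the L1 term and w_j² on the L2 term. Multipliers are floored at 0.01 so the
  scaled design stays well conditioned for the solver; at that level a
  "zero-penalty" gene is effectively unpenalized and is retained.
* **λ.min vs λ.1se.** The default minimum-deviance rule favors the larger
  signatures this strategy aims for, at the cost of null sparsity: on pure
  noise, λ.min regularly keeps a handful of small-coefficient features
  (the familiar behavior that motivates the 1-SE rule). When near-empty null
  signatures matter, use `lambda_rule="1se"` with ≥ 10 internal folds.
* **Wang–Mendel induction details.** Candidate rule weight is the product of
  each gene's winning membership; identical antecedent patterns merge by
  summed weight; a pattern claimed by both classes keeps the heavier class
  (tie → normal, conservative toward non-cancer) with weight equal to its
  share of the pattern total. Classification ties (equal class aggregates,
  including the nothing-fires case) fall back to the majority training class
  and are flagged `defaulted`.
* **Defuzzification.** The output is a class label, so the classifier
  compares class aggregates directly rather than computing a centroid; the
  signed aggregate difference in [−1, 1] is the ROC score.
* **In-fold selection.** Cross-validation reruns the *entire* pipeline —
  differential calling, intersection, elastic net, rule induction, and the
  normalization bounds — inside each training fold. A `global_selection`
  switch reproduces the optimistic design where features are selected once
  on all samples; it exists for comparison only, because the two designs can
  differ materially in reported accuracy.
* **Leave-one-out.** Requesting k ≥ n folds yields a leave-one-out partition
  (stratification is moot with singleton test sets); otherwise k shrinks to
  the smallest class size with a warning.
* **Quantile normalization.** External samples are mapped rank-by-rank onto
  the pooled empirical quantile function of the internal reference over the
  shared genes (average ranks for ties). The map is idempotent against a
  fixed reference.

## The synthetic-data generator

`fuzzsig.synth` emulates the statistical structure the pipeline assumes:
log2 expression is Gaussian around per-gene baselines drawn from U(2, 10)
with noise σ = 0.5; planted DEGs shift tumor means by ±3 log2 units (sign
random per gene). Methylation betas are Beta-distributed with precision 60
around locus means drawn from U(0.15, 0.85); planted DMG promoters shift a
random nonempty subset of their CpGs by ±0.4 (clipped away from the [0, 1]
boundary). CpG counts per promoter are Poisson(3); 10% additional decoy loci
fall outside any promoter to exercise the interval filter. Defaults plant
10% DEGs and 10% DMGs with a 5% joint overlap in a 400-gene, 30+30-sample
cohort; biomarkers are drawn from the joint set so the panel is genuine
signal. Each data type has its own RNG stream spawned from the master seed,
so runs are bit-reproducible and partially perturbable.

For external-validation studies, `simulate_external` regenerates an
independent expression cohort in which a chosen subset of DEGs ("unstable"
expression-only hits) has its effect reversed and a constant batch offset is
added; `subsample_loci` (default 1/18 of loci) and `add_expansion_noise`
(truncated Gaussian, σ = 0.05) provide sparse-array and noisy-expanded
methylation stand-ins.

**What the generator does not emulate:** gene–gene and CpG–CpG correlation,
count-based mean–variance structure of RNA-seq, bimodal beta distributions,
copy-number or purity effects, and realistic promoter overlap. Passing tests
therefore demonstrate correctness of the machinery and calibration under the
assumed model, not performance on real cohorts.

## Problem sizes

Tests and the reproduction script run the study at desk scale: 150–500
genes, roughly 600–1500 CpGs, 15–30 samples per class, 10-fold outer CV,
20 null seeds and 10 comparison seeds. These sizes keep every planted-effect
power calculation in the near-certain regime (e.g. Cohen's d = 6 at
n = 30/group for DEGs) so recovery rates are informative about correctness
rather than statistical luck.

## Data caveats

The packaged per-cancer reference tables reproduce the published lists as
printed. Note the published HNSC signature list contains 54 symbols although
the accompanying text reports 21 selected genes; the packaged fixture keeps
the printed 54-gene list.

## Known limitations

* Expression-only features enter the elastic net; methylation informs the
  candidate filter but not the classifier's inputs.
* Missing values are rejected, not imputed.
* Two classes only; no survival or subtype modelling.
* The fuzzy rulebase grows with training-set diversity (at most one rule per
  distinct antecedent pattern); no rule pruning is performed.
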