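# Methods

## Feature engineering

Internal coordinates are 1-based inclusive (the allele-specific caller
convention); BED input is converted at the boundary (`start+1`, `end`) and
converted back on export. Chromosome names are normalized by stripping the
`chr` prefix. Sex chromosomes are parsed and contribute gene-level
features, but are excluded from the genome-wide summaries (pLOH, AScore,
cna_burden) so that gender does not shift sample-level fractions.

**Gene copy number** is the (total, minor) pair of the overlapping segment
with the largest overlap length; ties go to the higher total copy number.
A length-weighted mean would be the obvious alternative, but it produces
non-integer copy numbers and dilutes short high-amplitude amplicons — the
exact objects this package looks for — so max-overlap with an
amplification-sensitive tie-break is the declared convention. Genes with no
overlapping segment stay missing; missingness is information (tumor-only
pipelines, uncovered contigs) and is routed natively by the boosted trees,
never imputed upstream.

**pLOH** is the fraction of assessable autosomal genome (segments with a
known minor allele) in LOH: minor CN = 0 with total CN ≥ 1; homozygous
deletions (total 0) are not LOH. Segment length is `end − start + 1`. If no
autosomal segment carries a minor-allele value the quantity is undefined
and an error is raised; the feature-matrix builder converts that to a
missing value.

**AScore** counts included autosomal arms whose length-weighted mean total
copy number, rounded, deviates from the rounded sample ploidy.
**cna_burden** is the autosomal genome fraction with total CN ≠ rounded
ploidy. Both are ploidy-relative rather than fixed-diploid, following the
aneuploidy-score and CNA-burden literature: a clean whole-genome
duplication scores zero on both. Acrocentric p-arms (13p, 14p, 15p, 21p,
22p) are excluded from AScore. All rounding everywhere is half away from
zero.

The packaged hg38 arm table is built from standard chromosome lengths and
centromere boundary positions; for each chromosome `p_end + 1 = q_start`.
The packaged cytoband table is a curated (synthetic-subset) list of
well-known oncogene-bearing bands for convenience; genome-wide band
analyses should supply a full UCSC-style table, which the loader accepts.

## Classifier

XGBoost (`binary:logistic`, `hist`, single thread for determinism) under a
protocol designed for extreme imbalance:

* **Folds** — stratified group k-fold: groups (tumor samples) are shuffled
  once per seed, then positive and negative groups are dealt round-robin,
  so positive-group counts per fold differ by at most one and no sample's
  rows ever straddle folds. Stratification is by sample-level positivity
  (whether the tumor has any cargo gene).
* **Search** — `n_search` random draws from: learning rate log-uniform
  [0.01, 0.3]; depth {3..8}; row/column subsample [0.5, 1]; min child
  weight {1, 5, 10}; positive-class weight {1, #neg/#pos}. Defaults
  (k = 10, 1000 draws, patience 10, ≤ 500 rounds) match the published
  protocol scale; tests and the acceptance study use k = 5 with 20 draws,
  which this cohort size saturates.
* **Early stopping** — on held-out auPRC, stopping after `patience` rounds
  without improvement; the winning configuration is refit on all data at
  the mean of the per-fold stopping rounds.
* **Metric** — step-wise average precision (sum of precision at each recall
  increment, ties grouped at one threshold), not trapezoidal PR
  interpolation, which overestimates under imbalance. auROC is the
  Mann–Whitney concordance with ties counted ½. Both are cross-checked in
  the tests against exhaustive-threshold / pair-counting oracles.
* **Sample level** — a tumor's score is the maximum gene probability (any
  cargo gene makes the tumor positive, so max is the matching aggregate);
  its truth label is "has ≥ 1 true cargo gene".

The copy-number-only baseline is a logistic regression on `total_cn` with
median imputation, exposed with the same predict interface and evaluated
under the same grouped folds, so the full-model/baseline comparison is
like-for-like. Honest held-out sample metrics come from out-of-fold
refits of the winning configuration.

## Typing

Focal amplification: `total_cn ≥ max(cn_min, ratio_min × ploidy)` with
cn_min = 5 and ratio_min = 2.25 — the near-diploid CN > 4.5 amplicon
seeding convention, scaled by ploidy so tetraploid genomes are not called
wholesale. Both knobs are config-exposed and recorded in output metadata.
A high cargo probability without focal amplification is vetoed to
`nofocal` (logged): the three classes stay mutually exclusive and anchored
to observable amplification. A single circular gene suffices to call the
tumor circular; class precedence is circular > noncircular > nofocal, and
the same precedence aggregates gene calls to cytobands.

## Cohort statistics

* The expression regression is fitted on TPM exactly in the linear form
  (no log transform), with cancer type as categorical contrasts; the
  two-sided p-value of the circular coefficient is BH-adjusted across
  testable genes (≥ 2 circular levels, more samples than parameters) and
  significance means FDR < 0.05.
* Fold change for an amplified sample is `(TPM + 1)` over the mean
  `(TPM + 1)` of non-amplified samples of the same gene. The class effect
  on the fold-change-vs-CN line is tested by comparing the pooled
  regression against the class-interaction regression with a nested
  ANOVA F-test.
* Odds ratios: cross-product `(a·d)/(b·c)` by default (errors on zero
  cells, pointing at the alternative); `fisher_cmle` gives the conditional
  MLE that matches the Fisher-test convention. p-values are two-sided
  Fisher exact.
* The Circle-Seq filter applies the criteria with their literal strictness:
  score > 50, discordant reads > 1, split reads ≥ 4, mean coverage > 4,
  coverage continuity < 0.1, length (end − start) > 10 kb.
* Percentages are printed to one decimal, rounding half away from zero.

Note that BH adjustment is monotone but **not** idempotent (re-adjusting an
adjusted vector multiplies by n/rank again); only monotonicity is treated
as an invariant.

## Simulator

What it emulates: per-arm baseline at the sample's integer ploidy
(2/3/4 at 70/20/10%, jittered ±0.05), arm gains/losses at 5% per arm, one
LOH tract per chromosome at 10%, purity uniform on (0.2, 1], and planted
focal events — circular at 30% of samples (CN 8–100), noncircular at 25%
(CN 5–12, subtype BFB/HR/Linear), 1–2 events of 2–10 consecutive genes.
Planted copy numbers are floored at the focal-amplification threshold for
the sample's ploidy, so planted events are always typeable and truth
classes equal the typing of truth probabilities. The deliberate CN overlap
between the two event kinds keeps copy number informative but not
sufficient — the designed analogue of the observed gap between a
copy-number-only model and the full model. Five percent of genes are
hotspots attracting 90% of circular events, which makes the
catalog-derived `freq_*` priors informative the way recurrent oncogene
cargo does in real amplicon catalogs. Expression is
`a·CN + b·cargo + type offset + d·purity + N(0, sd)` truncated at zero,
with a = 5, b = 50, d = 10, sd = 10. At the default 200 × 1000 scale the
gene-level cargo rate lands at a few per thousand, the intended imbalance
regime.

The dedicated expression-study generator (`simulate_expression_study`)
draws directly from the regression's data-generating process with a 10%
circular fraction and overlapping CN ranges between circular and
non-circular samples (noncircular amplification exists too); the overlap
keeps the CN and circular covariates separable so the boost coefficient is
estimated with usable precision. Baseline expression offsets (50/70/90 by
cancer type) keep zero-truncation negligible.

What the simulator does **not** model: read-level data, breakpoint
structure, subclonality, GC/replication-timing artifacts, or segmentation
noise. Passing tests therefore demonstrate that the pipeline recovers
planted structure under its own assumptions — not calling accuracy on real
tumors, which depends on upstream copy-number calling quality.

## Problem sizes and numerical choices

The reference study uses 200 samples × 1000 genes with 20 search draws and
5 folds; unit tests use 40 × 150 cohorts. Regression recovery uses
n = 500 samples and 20 seeds for the null-gene FDR check. Determinism:
every stochastic step seeds a NumPy generator from the user seed (plus
fixed stream tags), and XGBoost runs single-threaded with a fixed seed, so
identical inputs give bit-identical CV histories. Degenerate inputs have
defined behavior throughout: single-class metric calls raise, zero
predicted positives give missing precision, arms with no coverage are
skipped, genes without reference samples are skipped and logged.

## Known limitations

BFB/HSR amplifications with very high copy number are intrinsically
confusable with ecDNA from copy-number data alone; the classifier reduces
but cannot eliminate this. Low-copy ecDNA below the focal threshold is
invisible by construction (the veto). The shipped cytoband resource covers
only marquee oncogene bands. Exact reproduction of any published model's
weights is out of scope; the training framework, not a frozen model, is
the deliverable.
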