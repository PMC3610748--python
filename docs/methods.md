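# Methods

`genemdr` implements a multi-stage case-control analysis for candidate-gene
SNP panels: sequential quality control, permutation single-locus association
tests, LD-block haplotype likelihood-ratio tests, and a gene-based
multifactor dimensionality reduction (MDR) scan for within-gene and
between-gene interactions, with optional stratification of cases by a
Continuous Performance Test (CPT) sustained-attention endophenotype. A
seeded synthetic-cohort generator provides the test bed for every stage.

## Data model and conventions

Genotypes are coded 0/1/2 as the count of the minor allele, with the minor
allele defined on the **combined** case+control sample; loaders recode to
this convention and echo it in the output headers. Positions are 1-based
(VCF convention). Every SNP belongs to exactly one gene, enforced at load.
Missing calls are the sentinel -1.

Four canonical CPT strata split the cases at z = -2.5 on the unmasked (Zd')
and masked (Zmd') sensitivity scores: {Zd', Zmd'} x {below, at-or-above}.
Controls carry no CPT scores, so **all controls are retained in every
stratum**; each stratum compares its cases against the full control group.
Cases missing a measure drop out of both strata of that measure. QC is run
once on the overall sample and the cleaned, imputed data are reused for all
strata (a `qc_per_stratum` switch re-runs QC inside each stratum instead).

## Quality control

Rules fire sequentially, each evaluated on what survived the earlier rules,
and every removed entity is tagged with the first rule that fired:

1. samples with genotyping call rate (GCR) < 0.9;
2. SNPs with GCR < 0.9 in the case **or** control group;
3. SNPs with minor allele frequency < 0.01 (combined sample);
4. SNPs whose exact Hardy-Weinberg test in the **control group** has an
   FDR-adjusted p-value < 0.05 (Benjamini-Hochberg across the SNPs that
   survived rules 1-3).

All thresholds are strict inequalities and configurable
(`QcThresholds`). The HWE null is Levene's conditional distribution of the
heterozygote count given the allele counts; the p-value is the total mass of
tables at most as probable as the observed one. Small groups (2n <= 200) are
enumerated completely; larger groups use a Monte-Carlo version with 10,000
draws by default. Because permuting the alleles into genotypes induces
exactly the Levene distribution, the Monte-Carlo path samples heterozygote
counts from it directly — identical in law to allele permutation, far
cheaper — and reports p = (b+1)/(B+1).

Missing genotypes (defaults emulate ~0.57% of all calls) are imputed by
within-gene EM-haplotype posterior sampling: EM haplotype frequencies are
fitted on a window of up to 5 SNPs around the missing call (the whole gene
when it is that small; windows keep the phase space tractable for genes of
up to 21 SNPs) and the missing code is drawn from the haplotype-pair
posterior given the sample's observed genotypes in the window. Single-SNP
genes fall back to the SNP's marginal genotype distribution, also available
globally as an ablation (`method="marginal"`). Imputation never alters an
observed code and is reproducible from its seed.

## Single-locus tests

Per SNP: Pearson chi-square on the 2x3 genotype table (columns empty in both
groups are dropped so the statistic stays finite), Pearson chi-square on the
2x2 allele table, and the Cochran-Armitage trend statistic with additive
scores (0,1,2). p-values come from case/control label permutation with
p = (b+1)/(B+1) (10,000 permutations by default; one shared permutation
stream across SNPs per scan so results are reproducible from the master
seed). Asymptotic chi-square p-values are emitted as diagnostics only.
Benjamini-Hochberg FDR is applied separately per test type within each
analysis set, giving pFDR_SG / pFDR_SA / pFDR_ST.

Because the statistics are functions of small integer tables, permutations
tie the observed value with non-negligible probability and the permutation
p-values are slightly **super-uniform** under the null — conservative, never
anti-conservative. The calibration tests check exactly that: rejection rate
at the 0.05 level inside the binomial band, and no excess of small p-values.

## LD, blocks, and haplotype tests

Two-locus haplotype frequencies are estimated by EM from unphased genotypes
(collapsed to distinct multilocus patterns; 5 seeded restarts; convergence
when the largest frequency change drops below 1e-8, at most 1,000
iterations; the log-likelihood is non-decreasing by construction and is
property-tested). From them: Lewontin's D' = |D|/Dmax, the LOD (log10
likelihood ratio against linkage equilibrium), and a two-sided 90%
confidence interval on |D'| from the normalised likelihood over a 0.01-step
grid of D' in [0,1] with allele frequencies fixed at their sample values.

Gabriel-style blocks: a pair is "strong LD" when CI-low >= 0.70 and CI-high
>= 0.98, "strong recombination" when CI-high < 0.90; a contiguous run (up to
8 SNPs, the EM guard) is a candidate when >= 95% of its informative pairs
are strong LD; maximal non-overlapping candidates are chosen greedily by
size. All four thresholds are module constants.

Within each block, EM haplotype frequencies are fitted per group and pooled.
The **overall** test is LR = 2(lnL_case + lnL_control - lnL_combined) on the
observed-data likelihoods. The **individual** test collapses to
target-vs-other and uses the 1-df G statistic on EM-expected allele counts;
targets need an estimated combined count of at least 2 copies (the floor
keeps ~0.6%-frequency haplotypes while skipping singletons, and is flagged
in the output). Both take p-values from case/control label permutation; one
permutation stream serves the overall and all individual tests of a block,
with per-permutation EM warm-started at the pooled frequencies. pFDR_H is
BH-FDR over all overall-and-individual tests within the analysis set.

## Gene-based MDR

For every gene (within-gene scan) and every unordered gene pair
(between-gene scan), all SNP combinations of order 1-4 are evaluated by
10-fold class-stratified cross-validation. Training cells are labelled
high-risk when caseCount/controlCount >= T, with T the training-fold
case:control ratio; ties go high, cells with cases and no controls go high,
and empty or unseen cells predict control (the majority class). Testing
accuracy is **balanced** accuracy, (sensitivity + specificity)/2, because
the emulated design is unbalanced (893 cases : 554 controls); raw accuracy
is available via `balanced=False`.

Cross-validation consistency (cvc) of a combination is the number of folds
in which it is the best model **of its order** by **training** accuracy —
the selection the original MDR software repeats on each 9/10 training
portion. (Scoring fold-best by held-out accuracy instead makes cvc a noise
statistic: supersets of a true pair split the wins and even a strong planted
signal rarely exceeds 5/10.) The scan then compares the per-order champions
(each order's most consistently chosen model) by average testing accuracy;
this keeps overfit order-3/4 refinements of a true pair from displacing it,
mirroring how MDR presents one summary model per order. A within-gene
interaction requires a best model of order >= 2; a between-gene interaction
requires the model to span both genes; both require cvc/folds >= 0.8.

Candidates are validated by label permutation (1,000 permutations by
default): the identified combination is held fixed and re-scored by the same
CV procedure on each permuted labelling; the empirical p is (b+1)/(B+1).
BH-FDR runs separately over the within-gene and between-gene candidate
families per analysis set (pFDR_WG / pFDR_BG); candidates with pFDR < 0.05
are confirmed.

## Synthetic cohorts

The generator draws each gene's haplotypes from segment pools: an LD segment
is a small set of shared haplotypes with Dirichlet frequencies (high D'
within a segment by construction), segments are joined by free
recombination, and genes are independent (as for genes on different
chromosomes). Defaults mirror the emulated study design: gene sizes
[15,7,10,4,21,9,5,4,3,6], 893 cases / 554 controls, CPT stratum proportions
(Zd': 50% / 33% / 17% at-or-above / below / unmeasured; Zmd': 39% / 41% /
20%), and 0.57% random missingness. Numeric CPT scores are drawn uniformly
within the assigned side of -2.5 — only the side matters downstream.

Cohorts are sampled retrospectively: individuals are drawn from the pools,
disease status is Bernoulli in the penetrance (baseline prevalence 0.05 for
unmodelled genotypes — high enough to fill case quotas quickly, and only the
case/control genotype distributions matter for the analyses), and draws are
accepted into the case/control quotas until both fill.

Planted effects:

* **Rare risk haplotype** — accepted cases become carriers with probability
  0.0124 (controls 0.0): one chromosome's alleles at a designated triplet
  are overwritten with a haplotype absent from the pool. In the bundled
  scenario the risk triplet is chosen pairwise-compatible with the pool's
  gametes, so the planted copies do not create a fourth gamete and the
  Gabriel block remains intact — as a genuine in-block rare haplotype would.
* **Marginal-null epistasis** — an XOR-style pattern on a cross-gene SNP
  pair, double-centred with HWE weights so each SNP's marginal disease
  probability (hence its case/control allele-frequency contrast) is exactly
  null, then scaled so the optimal MDR rule reaches a target Bayes balanced
  accuracy (0.5 + total-variation/2, solved by bisection). Unreachable
  targets raise.
* **Marginal effect** — an additive single-SNP penetrance giving a
  case/control allele-frequency contrast near 0.36 vs 0.28.

All randomness flows from a single master seed through `SeedSequence`
spawning; there is no hidden entropy, and every stage is byte-reproducible.

What the generator does **not** emulate: realistic recombination maps or
coalescent genealogies, genotyping-error structure, population
stratification, or covariate confounding. Passing tests therefore
demonstrate the statistical machinery's correctness and calibration under
the stated design, not robustness to those real-data complications.

## Problem sizes in the test suite

The acceptance tests run the generator at the emulated study size
(893/554) for the recovery experiments, 300/300 for the 200-replicate null
calibration, with permutation counts of 200 (MDR and single-locus nulls),
1,999 (rare-haplotype LR tests) and 1,000 (acceptance-script MDR
validation) — sizes chosen so the whole suite completes in about a minute
while keeping Monte-Carlo error far from the decision boundaries. The
recovery and calibration experiments simulate with missingness 0: QC and
imputation are exercised separately, and on a 9-SNP panel a single missing
call already drops a sample's GCR below 0.9, while imputation could add or
remove copies of the planted rare haplotype and blur exactly the property
under test.

## Known limitations

* The D' confidence interval uses a fixed-margin profile likelihood grid;
  CI endpoints are reported on the 0.01 grid.
* Between-gene scans enumerate up to C(36,4) combinations for the largest
  gene pair at the default sizes; a full 10-gene, 84-SNP run is minutes of
  CPU, not seconds.
* The EM copy floor (2 copies) and the block-size guard (8 SNPs) are
  heuristics exposed in the configuration, not estimated from data.
* Interactions spanning more than two genes are out of scope, as are
  covariate-adjusted tests and reference-panel imputation.
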