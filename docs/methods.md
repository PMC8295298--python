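# Methods

This note documents the statistical model, the simulator, the numerical
choices and the known limitations of `pwascan`. Everything stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Effect-score model

The package's core statistic treats every alternate allele of a coding
variant *v* as an independent Bernoulli event that abolishes the function
of the gene copy carrying it, with probability *d<sub>v</sub>* ∈ [0, 1]
(the variant's damage probability; `damage_from_retention` converts a
functional-retention score *r* to *d* = 1 − *r*). For hard-called
genotypes *g<sub>v</sub>* ∈ {0, 1, 2}:

* dominant score = P(no damaging event) = ∏ (1 − d<sub>v</sub>)^g<sub>v</sub>;
* recessive score = P(at most one damaging event), the dominant score plus
  the exactly-one term Σ<sub>a</sub> d<sub>a</sub> ∏<sub>b≠a</sub> (1 − d<sub>b</sub>).

One minus the dominant score is the probability of a dominant-type loss
(≥ 1 damaged copy); one minus the recessive score is the probability of a
recessive-type loss (≥ 2 damaged copies, homozygous or compound-
heterozygous). This independent-Bernoulli-per-allele formulation is the
minimal model with the required semantics: scores lie in [0, 1] with
dominant ≤ recessive, decrease monotonically in any *d<sub>v</sub>*, treat
a het *d* = 1 variant as a certain single hit, and are phase-free (two het
variants count as two potential hits regardless of haplotype — array data
are unphased, and the ≥ 2-event definition does not require *trans*
configuration). For ≤ 10 alleles the implementation agrees with exhaustive
2^k enumeration to 10⁻¹².

Fractional (imputed) dosages are hard-called before scoring with
configurable thresholds (default: het band [0.5, 1.5), closed on the
left). Propagating dosage uncertainty through the product formula was
rejected to keep the enumeration oracle exact; hard-calling biases toward
no-damage, i.e. toward missed signal rather than false discovery. Missing
genotypes are likewise treated as homozygous reference, with a per-gene
missingness counter on the score matrix.

## Gene-level association test

For each gene and phenotype, four logistic regressions are fitted: a
covariates-only null, the null plus the (variance-standardized) dominant
score, plus the recessive score, and plus both. Likelihood-ratio tests
against the null give `p_dom` and `p_rec` (1 df) and `p_comb` (2 df; the
null hypothesis is that both score coefficients are zero). LRT was chosen
over Wald for the gene models because the combined null is a joint
two-coefficient hypothesis; the per-variant additive test (`gwas_variant_test`)
reports a Wald p-value to mirror standard GWAS output, and is gated at
minor allele count ≥ 20 (inclusive).

Numerical details:

* The design is intercept + variance-standardized numeric covariates;
  constant covariate columns are dropped (this automatically removes sex
  under a sex-restricted phenotype). The covariates-only null fit is
  shared across genes within a phenotype — it does not involve the gene —
  which makes genome-wide scans and the simulation suites tractable.
* Optimisation: Newton from the null fit's parameters, falling back to
  BFGS and then L-BFGS. A fit that still fails is reported with a missing
  p-value and excluded from the FDR family (never a silent 0 or 1, and
  never an imputed p = 1, which would deflate the q-values of other genes).
* **Minimum-informative gate.** A score column enters a model only if at
  least `min_informative` (default 20) individuals deviate from its modal
  value. With fewer, the chi-square reference for the LRT is untrustworthy:
  in the extreme of a single two-hit carrier, that carrier being a case —
  probability ≈ prevalence — produces p ≈ 0.03, a ten-fold type-I
  inflation at α = 0.05. This is the same calibration rationale as the
  variant-level MAC ≥ 20 gate. Gated columns are dropped and the result
  flagged `degenerate`; a model that loses all its columns reports p = 1
  with the flag (a constant column is the extreme case). When the two
  standardized scores are exactly collinear, the combined test uses the
  rank of the added columns as its df.
* Calibration, measured at n = 5,000 with 2,000 null genes under the
  default rare-heavy generator: combined-test type-I error roughly
  0.05–0.065 depending on the cohort seed (genes tested against one
  cohort share its labels, so their p-values are correlated and the
  empirical fraction swings more than binomial noise suggests), with
  near-uniform p-values. A residual finite-sample caveat: the
  *recessive-only* p-values remain mildly anti-conservative at this
  sample size even above the informative gate,
  because bimodal damage probabilities concentrate the recessive score's
  variation in a few extreme-leverage individuals; the machinery is exactly
  uniform on continuous scores and on common-variant genes (property-
  tested), and the issue shrinks as two-hit carriers accumulate at larger n.

FDR is Benjamini–Hochberg, applied per phenotype separately to the
dominant, recessive and combined p-value families (the correction families
are not merged across models; results tables carry all three q-values so
users can recombine). Inheritance is classified from the single-score
q-values (dominant / recessive / both / none at q < 0.05); direction from
the Cohen's d of the significant model, the smaller-p model breaking ties
when both are significant — risk iff d < 0 (cases score lower, i.e. carry
more damage). A zero pooled SD makes d degenerate: 0 when the group means
coincide, a signed infinity when two internally-constant groups are
separated.

## Region merging

Significant variant hits seed closed 1-based intervals [pos − 500,000,
pos + 500,000] (length 1,000,001 bp), significant genes seed
[cds_start − 500,000, cds_end + 500,000]; both clip at position 1.
Per chromosome, intervals sharing at least one base pair merge
transitively to a fixed point; under the closed convention a shared
endpoint is a 1 bp overlap and merges, while a 1 bp gap does not. Merging
is idempotent and permutation-invariant, the output disjoint and sorted,
and every seed lies in exactly one region (property-tested). Merging is
performed jointly across phenotypes into one shared region set, with
per-phenotype significance carried as annotation. A region is a *soliton*
when exactly one distinct gene in it is PWAS-significant and that gene's
best q-value is below 10⁻³ — the regions least confounded by linkage
disequilibrium. BED output converts to 0-based half-open coordinates on
write.

## Risk curves

For one gene and score layer, the cohort is partitioned at score
percentiles p ∈ (0, 0.5] per side; group size is floor(p·n) under a stable
ordering (ties at a threshold belong to the bottom group). Each group's
prevalence estimate is conservative: the 95% Wilson score interval for
k/n is computed, and the estimate is the baseline rate when the interval
covers it, otherwise the interval bound nearer the baseline. The estimate
is therefore never farther from the baseline than the naive frequency, and
null-gene curves hug the baseline (≤ 10% of grid points deviate at
n ≥ 20,000). The "most significant" partition scans candidate cutoffs —
all distinct score values, or a 2,000-point percentile grid above 10,000
distinct values — with a two-sided Fisher exact test; for a fixed
threshold, bottom-vs-rest and top-vs-rest are the same table with rows
swapped, so each threshold is tested once and the reported side is the
smaller group's. The scan minimum is reported only below a 10⁻³ display
gate, all scanned p-values are retained, and — being a minimum over many
correlated tests, unadjusted for covariates — it is exploratory, not
corrected evidence. Risk ratios are oriented with the larger prevalence in
the numerator (≥ 1 by construction; direction is reported separately) and
rounded to one decimal in reports only.

## Synthetic cohorts

The simulator emulates the structure the pipeline assumes, not any
particular population:

* Genotypes: Hardy–Weinberg, dosage ~ Binomial(2, f) per variant, no
  linkage disequilibrium. Allele frequencies default to a 70/30 mixture of
  log-uniform rare (10⁻³–10⁻²) and common (10⁻²–0.5) variants.
* Damage probabilities: bimodal Beta mixture with mass near 0 and near 1,
  reflecting predictors that are confident for most variants.
* Covariates: sex (Bernoulli ½), numeric standard-normal covariates
  (principal-component-like) and one-hot categorical covariates with a
  dropped reference level (batch/centre-like); defaults 1 + 4 + 2, a
  deliberate scale-down of a biobank-size covariate set.
* Phenotypes: latent damaging events are drawn per alternate allele as
  Bernoulli(d); dominant effects contribute their log-odds when the gene
  has ≥ 1 event, recessive when ≥ 2, additive per event; the logistic
  intercept is calibrated by bisection so realized prevalence matches the
  requested baseline (1–20% is the intended cancer-like range).
  Sex-restricted phenotypes label the ineligible sex as missing. Latent
  event counts are logged so recovery tests can condition on simulation
  truth.
* Cohort filtering: `apply_cohort_filters` counts each individual under
  the **first** matching exclusion reason in the caller's order, a
  declared convention that makes the per-reason counts a partition
  (remaining + Σ excluded = total, always).

What the simulator does *not* model — LD, relatedness, imputation error,
array batch artifacts, population stratification beyond generic numeric
covariates — bounds what passing tests show: they validate the statistics
under the model's own assumptions, not robustness to those confounders.

Problem sizes used by the packaged studies: the null-calibration suite
uses 2,000 genes at n = 5,000 (the acceptance script a 800-gene, n = 4,000
variant of the same study); the recessive-recovery study uses replicate
cohorts of n = 20,000 with one causal gene of eight rare (f = 0.015),
highly damaging (d = 0.95) variants whose two-hit carriers have odds
ratio 5 — a few-percent carrier mass, typical of a rare recessive
architecture — detected by the recessive gene model in essentially every
replicate while exome-wide-significant per-variant additive tests find it
in a strictly smaller fraction.

## Known limitations

* The effect-score aggregation is a declared model; other aggregation
  schemes (calibrated rather than probabilistic weights) would satisfy the
  same qualitative semantics.
* Recessive-model p-values are finite-sample anti-conservative for genes
  whose two-hit information rests on few extreme-leverage individuals (see
  above); interpret recessive-only hits at moderate n with care.
* No mixed-model or relatedness correction; no X-dosage compensation
  model; risk curves ignore covariates by design.
* The Fisher-scan best cutoff is exploratory (minimum over correlated
  tests); the stored scan allows user-side correction.
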