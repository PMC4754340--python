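# Methods

`tagfun` implements the statistical machinery used to dissect a GWAS locus
after the initial discovery scan: combining per-study effect estimates,
testing whether the lead (tag) SNP's behaviour across ancestries is
consistent with local linkage disequilibrium, asking whether a regulatory
SNP modifies transcription-factor/target coexpression, and scoring what each
allele does to binding and splicing motifs. This note records the models,
the defaults, and the choices made where the design was genuinely open.

## Association model

Case/control association uses additive allele-dosage logistic regression:

    logit P(case_i) = alpha + beta * dose_i + gamma' * z_i

where `dose_i` in [0, 2] counts copies of the effect allele (fractional for
imputed posterior means) and `z_i` are covariates (principal components,
conditioning-SNP dosages). The fit is maximum likelihood by iteratively
reweighted least squares, tolerance 1e-8 on the log-likelihood, at most 25
iterations. Inference on `beta` is a Wald test; an expected-dosage score
test (`score_assoc`) is available and agrees asymptotically. Wald is the
default because it directly yields the OR and 95% CI records the summary
tables carry. Quasi-complete separation and non-convergence produce a
flagged record with P = NA rather than an exception, matching how GWAS
toolchains report unfittable SNPs.

One-sided P values are the halved two-sided P when the fitted effect matches
the prespecified direction (risk, i.e. beta > 0), and 1 minus the half
otherwise. Published replication pipelines do not always state which
one-sided construction they use; this halving convention is ours and is
documented rather than asserted as anyone else's.

Samples with a missing dose, status, or covariate at a given test are
dropped complete-case and the count logged.

## QC filters

`apply_qc` applies, in fixed order: sample call rate (missingness > 0.02
removed), per-sample inbreeding |F| > 0.05, SNP missingness > 0.05,
MAF < 0.01, Hardy-Weinberg deviation P < 1e-4 (chi-square, computed over all
samples since the QC runs pre-analysis; an exact mid-P test is a possible
extension), and case/control differential missingness P < 0.05. All
thresholds are `QcThresholds` fields. Removed SNPs are attributed to the
first rule that triggers, so the per-rule exclusion counts sum to the total.

Per-sample F is 1 - observed/expected heterozygosity over polymorphic SNPs.
This estimator needs genome-scale marker counts: on a narrow locus panel it
is essentially noise, so the rule is only applied when at least 50 SNPs are
available (logged when skipped).

An imputation `info` column, when present in input tables, can be used as a
pass-through filter (info < 0.3); imputation itself is out of scope.

## Fixed-effects meta-analysis

Per-study effects are log odds ratios with SEs. Printed "OR (95% CI)" cells
are inverted with se = (ln hi - ln lo) / (2 z), z = 1.959964 (the meta-
analysis software convention, not 1.96). A cell whose point estimate is not
the geometric midpoint of its interval beyond printing tolerance
(|ln(OR^2/(lo*hi))| > 0.02) triggers a warning: such intervals were likely
not Wald-normal and round-trips on them are unreliable. Because printed ORs
carry two decimals, reconstructed combined ORs are only expected to match to
about +-0.01.

Combination is inverse-variance fixed effects: beta = sum(w_i b_i)/sum(w_i),
w_i = 1/se_i^2, se = 1/sqrt(sum w_i). Heterogeneity: Cochran's Q on k-1 df
and I^2 = max(0, (Q-(k-1))/Q) * 100, floored at zero (reported I^2 is never
negative). SNPs with I^2 > 50% are excluded by `heterogeneity_filter`.
Genomic control is lambda = median(chi^2) / 0.45494.

The locus fixture tables ship the printed per-study and combined cells; the
combined *conditional* P columns cannot be recomputed from printed cells
(per-study conditional SEs are not published) and are carried as data only.

## Constrained haplotype resampling

The trans-ethnic consistency question: given the causal SNP's genotype
counts in cases and controls, how often would the *tag* SNP's association
look weaker than actually observed, under the local LD of an admixed
reference panel? Each replicate assigns every individual their causal
genotype (so causal genotype counts match the input exactly — asserted
inside the sampler on every replicate) and draws the individual's two
haplotypes from the panel conditional on the causal allele each haplotype
must carry; the tag allele rides along. The replicate tag P comes from a
chi-square test of homogeneity on the tag allele 2x2 table (a 2x3 genotype
table is available via `table="genotype"`; which table the original analysis
used is not stated, and the allele table is the default).
`frac_less_significant` counts replicates with P *strictly* greater than the
observed tag P; ties count as not-less-significant.

Sampling is with replacement within causal-allele stratum. Literal
without-replacement sampling is infeasible whenever the design needs more
haplotypes than the panel holds (an admixed reference of ~244 haplotypes
cannot supply ~3,100 without replacement), so replacement sampling that
preserves the stated constraint — exact causal genotype counts — is the
default; a `without_replacement` flag exists for designs small enough to
honour it, in which case the draw is shared across cases and controls.

## Genotype-dependent coexpression

Genotype class collapses dosage to carrier status: class 1 iff dose >= 0.5
(0 risk alleles vs >= 1), because the homozygous-risk class is too rare to
model separately. Both expression vectors are standardized internally to
mean 0, variance 1. Two nested OLS models are compared:

    reduced: target ~ tf + class
    full:    target ~ tf + class + tf:class

with LRT = n * ln(RSS_reduced/RSS_full) on 1 df (the Gaussian likelihood-
ratio statistic; an F-test variant `coexpr_f_test` is provided). Thanks to
standardization the interaction coefficient `delta_hat` estimates the
difference in Pearson correlation between classes (r_class1 - r_class0 up to
O(1/n)), and per-population (delta_hat, delta_se) pairs pool by the same
inverse-variance rule as the GWAS effects. The one-sided P assumes
*attenuation* in the risk class — the interaction pushing the risk-class
slope toward zero, i.e. a negative interaction when the base correlation is
positive; the direction is configurable since published one-sided use rarely
defines the side.

Correlation tests use the asymptotic t = r sqrt((n-2)/(1-r^2)) on n-2 df,
for both Pearson and Spearman (average ranks for ties), with an optional
percentile-bootstrap P alongside. Note: a published Spearman r = 0.22 at
n = 358 is inconsistent with its published P = 4.3e-9 under this t
approximation (which gives ~3e-5); no attempt is made to reproduce that P.
Per-class correlations are reported as Pearson, matching the regression
parameterization; whether published per-class values were Pearson or
Spearman is unstated.

eQTL and exon-usage analyses are OLS of (optionally log2-transformed)
expression on dose plus covariates with a t-test on the dose term. The
TF expression-presence rule keeps genes whose value exceeds 0.01 in strictly
more than 75% of samples.

## Motif and splice-element scoring

A PWM is a positions x {A,C,G,T} probability matrix; JASPAR count matrices
convert with an additive pseudocount of 0.25 per cell (configurable), and a
TRANSFAC-dialect reader is included. LOD at an offset is the summed
log(p_pos(base)/background(base)); the log base defaults to 2 and is
configurable — allele comparisons are sign/rank based, hence base-invariant.
Background defaults to uniform 0.25. Scans cover both strands by default;
minus-strand hits score the reverse complement with offsets reported on the
forward query.

`allele_disruption` substitutes each allele at the SNP offset, takes the
best LOD over windows *spanning the SNP* (so the delta isolates the
allele's effect), and reports delta = alt_best - ref_best; it is
antisymmetric under allele swap by construction. Splice-enhancer scanning is
an exact forward-strand match of hexamer motifs against each allele-resolved
sequence of a one-slot template like `CCCAG[G/T]AC`; overlapping hits are
kept, since the biological point is precisely that the two alleles complete
two overlapping elements.

## Synthetic data

The generator produces the study shapes the pipeline assumes, not realistic
genomes:

- **Haplotype panels**: two focal variants with haplotype frequencies
  solving p_AB = p_A p_B + D, D = sign * sqrt(r2 * p_A q_A p_B q_B), then a
  multinomial draw. Risk alleles are positively coupled by default
  (`negative_d` flips the sign), matching a tag/causal pair whose risk
  alleles co-occur. Requested r2 beyond the maximum attainable for the
  marginals raises a feasibility error reporting that maximum.
- **Case/control studies**: individuals pair two random panel haplotypes;
  status follows the additive log-odds model with a baseline prevalence of
  0.10 (configurable; retrospective designs never state one), and rejection
  sampling fills the requested case/control counts — simple and unbiased at
  these scales.
- **Expression pairs**: per-class bivariate normals with unit variances and
  the specified class correlations.
- **Null GWAS statistics**: i.i.d. 1-df chi-squares.

What this does *not* emulate: multi-locus haplotype structure beyond the two
focal variants, coalescent genealogy, genotyping/imputation error, expression
count noise, batch effects, or population stratification. Passing tests
therefore demonstrate that the statistics are implemented and calibrated
correctly under their own assumptions, not that real cohort data would give
the published numbers.

## Problem sizes and determinism

Every generator takes an explicit seed and is bit-reproducible. The test
suite exercises the published-scale designs where they are cheap (203/1,363
admixed study, 300/58 expression classes, 10,000 null SNPs) and uses
reduced replicate counts where full published scale adds nothing but time:
sampler-oracle equivalence runs 50,000 replicates on a 20-haplotype panel;
LD-monotonicity uses 2,000 replicates x 20 seeds x 4 LD levels; coexpression
calibration uses 2,000 null data sets (1,000 in the acceptance script) and
1,000 recovery seeds (500 in the script). The resampling emulation in the
acceptance script redraws its "observed" data set from the model each run,
so its percentage varies across seeds far more than a fixed-data-set
analysis would — that spread is inherent to emulating a single-data-set
statistic with synthetic inputs.

## Known limitations

- Only two-study meta-analysis is exercised against printed tables, though
  the estimator takes any k; random-effects and sample-size-weighted schemes
  are out of scope.
- The logistic fitter does not implement bias-reduced (Firth) estimation,
  so rare-variant separation yields NA rather than a penalized estimate.
- Bayesian fine-mapping (credible sets) and stepwise multi-SNP conditional
  search are out of scope.
- The VCF writer emits minimal hard-call records; dosage precision beyond
  hard calls survives only through the dosage-TSV path.
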