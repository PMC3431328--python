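# Methods

This note documents the statistical procedures the package implements,
the assumptions behind its synthetic-cohort generator, the numerical and
design choices that were genuinely open, and what the test suite does and
does not establish.

## Score construction

The risk score is an unweighted count of risk alleles over the SNP panel.
Construction is four explicit steps — orientation, imputation, summation,
stratification — because each carries a convention worth pinning down:

* **Orientation.** Stored calls may count either allele of a SNP; they
  are re-expressed as risk-allele counts (`2 − call` when the counted
  allele is not the risk allele) before anything else. The risk-allele
  designation itself is data, carried by the risk table, and validated
  against its defining direction (+TG, +LDL-C, −HDL-C).
* **Imputation.** A missing call is replaced by the mean of the
  non-missing calls for that SNP *within the individual's self-reported
  ethnicity*, rounded to the nearest whole number. Rounding at .5 is
  half-away-from-zero (so a group mean of exactly 1.5 fills as 2);
  "nearest whole number" is ambiguous at ties and this choice is
  documented and tested rather than left to the platform default.
  Fill means are computed on the post-exclusion analysis cohort, so the
  score is internal to the analysed sample. A (SNP, ethnicity) cell with
  no observed calls is an error, not a silent fill.
* **Stratification.** Quartiles and the median split are assigned within
  ethnicity, because allele frequencies and lipid levels both differ
  across groups and pooled strata would confound score with ancestry.
  Quartile cut points are type-7 empirical quartiles; a score exactly at
  a cut point goes to the *lower* quartile, so with integer scores ties
  cluster downward and per-stratum quartile ranges may overlap. The
  median split puts scores at or below the stratum median in "low".

A weighted (effect-size) score is deliberately out of scope.

## Analysis models

All traits are analysed on the natural-log scale except LDL-C (raw
mg/dl); right-skew motivates the log, and the package refuses
non-positive values in log traits rather than guessing. Baseline models
adjust for age, sex, self-reported ethnicity (fixed-effect indicators;
no ancestry principal components) and BMI. The one-year models adjust
for the baseline trait value, age, sex and ethnicity — **not** BMI,
matching the convention that conditioning on the baseline trait already
captures adiposity-driven level differences; `include_bmi=True` restores
it. Reference levels: sex = F, arm = placebo, ethnicity = the largest
observed group.

The general (2-df) genotype test is an extra-sum-of-squares F test of
the 3-level genotype factor against the covariate-only model, equivalent
to a Type-III test for these balanced-by-construction designs. The
partial correlation is derived from the term's Wald t,
r = sign(β̂)√(t²/(t²+df)) — the source analyses never define it, and this
is the standard conversion.

Arm-stratified one-year effects are produced by refitting within each
arm rather than by linear combinations of the pooled model, letting each
arm carry its own covariate coefficients and residual variance; both
routes agree in expectation and a test checks their consistency. The
interaction p-values are per-term Wald tests; a joint 2-df F test of
both product terms is available as an option.

Confidence intervals use the normal 1.96 multiplier rather than a t
quantile; at the cohort sizes this package targets (thousands) the
difference is far below reporting precision. Adjusted (least-squares)
means are predictions at continuous covariates' sample means with other
factors weighted by observed proportions; for log traits the mean and CI
bounds are exponentiated (geometric means), with the CI built before the
back-transform. The extreme-quartile percent difference is reported as
the integer-rounded magnitude of 100·(Q4−Q1)/Q1, the direction being
read from the means themselves.

Missing trait or covariate values are handled by complete-case analysis
within each model, with the n used always reported.

## Quality control

Exclusions: individuals flagged for baseline lipid-lowering medication,
individuals present in only one input table, and SNPs with call rate
below 0.94 (configurable), each counted in the exclusion report.
Hardy-Weinberg equilibrium is tested per (SNP, ethnicity) stratum by a
1-df chi-square goodness-of-fit at the sample allele frequency (an exact
test is available for low minor-allele counts); failures are *flagged*
below p = 0.001, never auto-dropped — HWE violation can reflect
genotyping error but also real structure, and dropping is an analyst
decision. QC runs after the medication exclusion, on the analysis
cohort; the report records this ordering. Monomorphic strata return
p = 1 with a flag rather than an error.

The Friedewald calculation (LDL-C = TC − HDL-C − TG/5, mg/dl) returns a
missing marker above TG 400 mg/dl (4.5 mmol/l), where the TG/5 VLDL
approximation fails and direct measurement would be needed.

## The synthetic-cohort generator

The generator produces the *minimal* data-generating process the
analysis assumes; its defaults are the package's reference study
conditions.

* **Population.** Five self-reported ethnic strata at proportions
  0.55/0.21/0.17/0.04/0.03; age ~ N(50, 9) truncated to [25, 85],
  BMI ~ N(33.5, 6) truncated to [20, 60], 32% male — an overweight,
  middle-aged, prediabetic trial population.
* **Genotypes.** Risk-allele counts are Binomial(2, f) per (SNP,
  ethnicity) — HWE within stratum by construction — at frequencies drawn
  once (fixed internal seed) with moderate logit-scale ethnic divergence,
  clipped to [0.05, 0.95]. No linkage disequilibrium between panel SNPs
  and no admixture. Missing calls are completely at random at rate 0.033
  (a 96.7% genotyping success rate); medication flags are Bernoulli(0.048).
* **Traits.** On the analysis scale, trait = intercept + covariate terms
  + centred genetic contribution + N(0, σ); exponentiated for log
  traits. Intercepts and residual σ come from typical trial medians and
  IQRs (σ = IQR-of-logs/1.349); the genetic contribution is centred at
  its population expectation so injected effects do not shift trait
  medians. Default per-allele effects (e.g. +0.026 ln TG, +1.0 mg/dl
  LDL-C, −0.011 ln HDL-C) are applied uniformly across the panel, so the
  score-level slope equals the per-allele value — the property the
  recovery suites verify. In composition mode (default), total
  cholesterol is derived as HDL-C + LDL-C + TG/5, making the Friedewald
  identity exact; raw-scale traits are floored at 1 mg/dl to preserve
  positivity in extreme draws.
* **Follow-up.** On the analysis scale, y1 = m + ρ(y0−m) + arm effect +
  interaction(arm)·(GRS − mean GRS) + N(0, σ), with ρ = 0.6 for every
  trait by default. One-year residual variances are not observable from
  published summaries, so σ reuses the baseline value — an assumption,
  flagged here. The GRS is centred so an interaction tilts the
  within-arm slope without shifting the arm mean; interaction and
  stratified estimates are unaffected by the centring. Default
  interactions place +0.87 mg/dl/allele (LDL-C) and +0.030 ln/allele
  (small LDL particles) in the lifestyle arm. One-year values are
  generated from the *true* complete-data score, so recovery tests
  measure the whole analysis path — imputation included — against an
  exactly known target.
* **Seeding.** One root seed; per-stage child streams derived by
  `SeedSequence.spawn` in a fixed documented order, so identical configs
  give byte-identical studies and stages can be re-run independently.

What passing tests do **not** show about real data: the generator has no
LD, no admixture or cryptic relatedness, no informative missingness, no
measurement error in covariates, no visit-to-visit biological drift
beyond the single carryover parameter, and independent residuals across
traits (apart from the cholesterol composition identity). Calibration
and recovery results transfer to real cohorts only to the extent those
assumptions hold.

Under these noise levels a 0.9 mg/dl/allele lifestyle interaction at
n = 3000 is estimated without bias but with moderate power (single-run
Wald p frequently above 0.05); the recovery criteria are therefore about
bias over many seeds, not single-run significance.

## Numerical choices

The least-squares engine uses pivoted QR; rank deficiency raises an
error naming the collinear terms rather than silently dropping them.
Wald p-values use the t distribution with n − p degrees of freedom;
nested models are compared by the extra-sum-of-squares F. The engine is
plain numpy/scipy so the 5000-replicate calibration suites run in
seconds; statsmodels serves as an independent oracle in the tests, never
as the implementation. Problem sizes in the calibration suites (200
seeds at n = 3000 for recovery; 5000 replicates at n = 1000–1500 for
type-I error; three replicates of 10,000 per stratum for the HWE scan)
were chosen to put Monte-Carlo error well below the tolerances being
checked while keeping a full run to a few minutes on one CPU.

## Known limitations

* The bundled 32-SNP panel is a synthetic stand-in (its source-trait
  composition — 11 LDL-C, 10 HDL-C, 7 TG, 4 HDL-C+TG — matches the
  meta-analysis panels this kind of score is built from); real analyses
  must supply their own risk table.
* Only biallelic, unphased, autosomal-style genotypes; no multi-allelic
  support, no reference-panel imputation.
* Identity-link least squares only: no mixed models, robust standard
  errors, or survival endpoints.
* The percent-difference convention reports magnitudes; consumers
  needing signed values should read the quartile means directly.
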