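# Methods

## The measurement model

Relative sperm telomere length is a ratio of amplification targets: the
telomeric repeat (Tel) against a single-copy nuclear reference
(Albumin, ALB). Each plate carries a 7-point 1:2 serial dilution
(20, 10, 5, 2.5, 1.25, 0.625, 0.3125 ng) per target; the standard curve
is the least-squares fit of Ct on log10(input mass), the amplification
efficiency is `E = 10^(−1/slope)` (perfect doubling gives slope
≈ −3.3219 and E = 2), and the calibrator Ct is the *fitted* curve value
at 5 ng — not a raw well — because the anchor is defined as the standard
curve's 5 ng equivalent. The Pfaffl ratio

    STL = E_tel^(Ct_cal,tel − Ct_tel) / E_alb^(Ct_cal,alb − Ct_alb)

accommodates unequal efficiencies; with E_tel = E_alb = 2 it reduces
exactly to the classical 2^ΔΔCt form (a unit-tested identity). STL is
analyzed on the natural-log scale; the log base only rescales
coefficients by a constant and is a documented convention.

### Triplicate QC

Two discard rules are implemented:

* `literal_5pct_sd` (the `qc_triplicates` default): discard any well
  whose deviation from the triplicate mean exceeds 5% of the triplicate
  SD (sample SD, n−1 denominator, configurable). This rule is
  pathological by construction: a triplicate whose three values are not
  all equal always has at least two wells deviating by more than
  0.05·SD, so any real noise flags the set unusable (< 2 survivors).
  It is kept verbatim because it is the stated rule, but it cannot be a
  working pipeline default.
* `cv_threshold` (the pipeline default, threshold 0.05): keep the
  triplicate when its coefficient of variation is within the threshold,
  otherwise drop the single most deviant well and re-check the
  remaining pair; a pair still over threshold is unusable. This is the
  natural reading of "5% of" as a fraction of the mean and behaves
  sensibly under Gaussian Ct noise.

Neither mode is asserted to be what any particular laboratory did; the
mode and threshold are recorded in the output.

### Plate effects

Where log STL is the *outcome*, models carry a per-plate random
intercept; where it is the *exposure*, log STL is first residualized on
plate indicators (within-plate centering, whose residuals sum to zero
per plate). The random-intercept model is estimated by profiled REML:
with a single grouping factor the marginal covariance is block diagonal,
every GLS cross-product reduces to a rank-one group-sum correction, and
the restricted likelihood is maximized over the scalar variance ratio
λ = σ²_plate/σ²_residual (bounded scalar search on log λ, with the λ = 0
boundary checked explicitly). At λ = 0 the fit coincides with OLS
exactly. Fixed effects use Wald normal-theory CIs and p-values; OLS
models use t-based inference with n − p degrees of freedom. Both cores
are cross-checked in the test suite against statsmodels (OLS to
machine precision; MixedLM to ~1e-6 on coefficients).

### Primer product model

The predicted telomere amplicon length comes from the maximal perfectly
complementary antiparallel 3'-terminal overlap of the two primers:
product = len(a) + len(b) − k for the largest k with
revcomp(a[−k:]) = b[−k:]. For the shipped Telg (40 nt) / Telc (42 nt)
pair the maximal overlap is 3, giving 79 bp. Internal mismatches,
thermodynamics and genomic templates are out of scope (the ALB amplicon
anneals to genomic DNA and cannot be predicted from its primers alone).

## Genotype QC and scores

Subjects with call rate strictly below 80% are discarded (9/11 SNPs
= 81.8% survives). Hardy–Weinberg is tested per SNP with the 1-df
chi-square against expectations at the observed allele frequency; an
exact test (conditional heterozygote distribution) is available for
rare alleles. SNP-level call rates are reported but no SNP is dropped
automatically. Genotype strings are unordered (`C/A` ≡ `A/C`).

The unweighted teloscore sums effect-allele dosages (0–22 over 11
SNPs); the weighted score multiplies dosages by literature per-allele
effects (weights are configuration, never re-estimated from the cohort
— that would overfit). Scaled variants divide by the number of
genotyped SNPs and multiply by 11, using the same formula for both
score types. Quintiles are rank-based with minimum ranks, so ties fall
into the lower category and category counts differ by at most one
without ties.

The shipped panel file carries the 11 canonical telomere-length loci
with literature-style placeholder MAFs, effect alleles and weights for
European-ancestry populations; all three are explicitly configurable
and any real study must substitute its own values.

## ABCD banding

Bands are half-open: A strictly below the 5th centile, B in [p5, p50),
C in [p50, p95), D at or above p95. The interval convention at the
boundaries is a documented choice (the verbal definition "ranging from
5th to 50th" is ambiguous). The pseudo-continuous mapping defaults to
the integer assignment A..D → 1..4; an `interpolated` mode adds the
linear position within the band (A uses value/p5; D uses 1 − p95/value,
both monotone and bounded), so interpolated scores floor to the integer
ones. ABCD = sum over the four banded parameters (4–16 in integer
mode); ABCD_mot = the two motility bands (2–8). Default centiles are
the WHO 2010 reference distribution (p5/p50/p95); cohort-empirical
centiles can be supplied instead via the config file.

## The association scan

Exposure × outcome enumeration: residualized log STL (linear + quintile
contrasts 2nd–5th vs 1st) and the two scaled teloscores against the
nine semen parameters plus ABCD and ABCD_mot; scores and each SNP
(additive + codominant with the major-allele homozygote as reference)
additionally against log STL under the plate random intercept. All
models adjust for age (years, continuous) and smoking (binary);
missingness is complete-case per model with n recorded per record. A
genotype class absent from the analysis sample collapses its codominant
contrast rather than producing a degenerate column. Every model that
cannot be fitted (constant or collinear exposure, < 10 complete cases)
is logged as a skip; nothing is dropped silently.

Multiple testing: the SNP scan is flagged at 0.05/33 ≈ 0.0015
(11 SNPs × three inheritance coefficients: one additive, two
codominant); score and STL records are flagged at nominal 0.05, with
each record's threshold stored in the output. The 0.05/33 correction
controls the family-wise error of one outcome's 33 SNP tests at
(1 − 0.0015)^33 ≈ 5%; across the ~363 SNP records of a whole scan the
expected number of null flags is ≈ 0.5, so "no flags anywhere" is not a
guarantee Bonferroni makes, and the calibration audit checks the
per-family rate.

## The synthetic cohort generator

The generator's defaults are the study conditions the analysis targets:
599 subjects; ages Normal(34.8, 7.5) clipped to 18–59; 32% smokers;
HWE genotypes at the panel MAFs with 1.5% background per-genotype
missingness plus a 2.5% "degraded-DNA" subject fraction at 50%
missingness (uniform missingness alone cannot produce subjects below
the 80% call-rate filter while keeping a ~98% average SNP call rate);
latent log TL = intercept + β·(total effect-allele count) + N(0, 0.25)
with β = 0 by default (a null telomere effect); semen parameters with
the cohort-scale means/SDs and per-year age slopes of a consecutive
andrology population (progressive motility −0.31 %/year), clipped to
their valid ranges; and a default-zero TL→sperm effect. For generation
only, missing genotypes contribute their population expectation
(2 × effect-allele frequency) to the latent dosage.

qPCR wells follow Ct = target intercept + plate offset −
log(input·TL)/log(E) + N(0, 0.05), the latent TL entering TEL wells
only, with per-(plate, target) offsets (SD 0.3) applied to *sample*
wells only: an offset shared with the plate's standard curve would
cancel exactly in the Pfaffl calibration, so this structure is what
gives measured log STL a genuine plate random effect. Plates hold 13
subjects (6 sample wells + 14 standard wells of a 96-well layout). One
master seed spawns independent per-stage streams, so identical configs
are byte-identical on disk and stages are reproducible in isolation.

What the generator does *not* emulate: linkage disequilibrium between
panel SNPs, population stratification, realistic joint distributions of
semen parameters beyond first moments (clipping percentages at [0, 100]
biases means slightly at extreme configs), duplicate-sample genotyping
runs, or subjects lacking sperm DNA for STL measurement. Passing tests
therefore demonstrate correctness of the computational pipeline under
its stated assumptions, not robustness to those real-data features.

## Audit scale and numerical choices

The repeated-simulation audits run 500 cohorts of 599 subjects for null
calibration (nominal p < 0.05 rate within 0.05 ± 0.02; ≥ 95% of
(cohort, outcome) Bonferroni families with zero flags) and 500
replicates for CI coverage of the injected TL and age effects (band
93–97%). The TL-effect audit fits fully-genotyped subjects only: a
partially observed dosage sum is an errors-in-variables exposure and
attenuates the slope, which is a property of the audit design rather
than of the estimator. The analysis driver `06_calibration.py` runs a
100-replicate pass for narrative output.

Standard curves require ≥ 3 distinct positive masses; efficiencies are
sanity-banded to (1, 4) at quantification time. Rank-deficient or
constant designs are model errors naming the offending term. REML λ is
searched on log λ ∈ [−12, 10]. Quintile categorization warns on fewer
than five distinct values and assigns everything to category 1 for a
constant vector.

## Known limitations

The real cohort behind this design is not publicly deposited, so no
claim is made of reproducing its coefficient estimates; the pipeline
reproduces the *procedures* and validates them on generated data. The
literal triplicate rule is unusable as stated (see above). Wald
normal-theory p-values for mixed-model fixed effects are mildly liberal
with few plates; with the default ~47 plates the effect is negligible,
and the null-calibration audit confirms the realized type-I rate. The
pseudo-continuous ABCD construction is a reconstruction; both offered
modes are documented, and composite results in integer mode are
insensitive to the within-band choice.
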