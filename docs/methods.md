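# Methods

`genelife` implements a gene–lifestyle joint-effect analysis of incident
hypertension in a 3-year follow-up cohort, together with a synthetic cohort
generator that makes every stage testable without access to individual-level
data.

## Outcome definition

Incident hypertension at follow-up is defined as SBP ≥ 140 mmHg or
DBP ≥ 90 mmHg, or use of antihypertensive medication within the two weeks
before the follow-up visit, among subjects hypertension-free at baseline.
`derive_outcome` is the single source of truth; cohort validation rejects
any table whose `hypertension` column disagrees with it.

## Lifestyle score

Five factors, each dichotomised healthful (1) / unhealthful (0) and summed
to a 0–5 score, grouped 0–1 unhealthful, 2–3 intermediate, 4–5 healthful:

- **Diet** — a 9-item food-frequency CHEI sub-score. The eight beneficial
  foods (whole grains, fish, eggs, dairy, vegetables, fruits, bean
  products, nuts) score daily=4 … never=0; red meat is reverse-scored.
  The stated per-item mapping gives a theoretical range of 0–36; the
  source cohort's observed range (3–28) is treated as an empirical fact,
  not a constraint. Healthful diet = CHEI ≥ 17 (the published fixed
  cutoff, default) or the cohort's own 60th percentile
  (`chei_cutoff_mode=empirical_top40pct`).
- **BMI** — healthful iff 18.5 ≤ BMI < 24. The verbal rule ("18.5–23.9
  healthful, <18.5 or >24 unhealthful") leaves (23.9, 24.0) undefined; the
  band is implemented closed below / open above at 24.0 so every value is
  classified. The sensitivity rule (`bmi_rule=sensitivity25`) moves the
  upper bound to 25 kg/m² (WHO overweight cutoff).
- **Smoking** — healthful iff never smoked or quit ≥ 30 years ago.
- **Physical activity** — healthful iff IPAQ moderate or high.
- **Drinking** — healthful iff at most 12 drinks in the last year
  ("more than 12" defines current drinking, so 12 is healthful).

## Genetic risk score

Each of the 13 SNP loci contributes the effect value of the subject's
genotype, with the non-risk homozygote as reference (contributing 0); the
GRS is the sum over loci, grouped into tertiles (ties broken by stable
subject order so group sizes differ by at most 2; if every GRS is identical
the partition is degenerate and everyone is assigned "low" with a warning).

Effect values are estimated in-sample, one locus at a time: an unadjusted
regression of the configured outcome (default: logistic on incident
hypertension; option: linear on follow-up SBP) on the two genotype dummies.
Whether the source analysis estimated these per-dummy effects adjusted or
unadjusted, and against which outcome, is not documented; both options are
exposed and neither is asserted as the original. Monomorphic loci, empty
genotype cells and separation yield zero effects with a logged warning.
User-supplied weights (e.g. published GWAS betas) can replace the in-sample
estimator via `GrsModel.from_effects`.

## Association models

Logistic regression for hypertension and ordinary least squares
(identity-link Gaussian) for follow-up SBP/DBP, with Wald 95% intervals.
Follow-up pressure is the response, with baseline SBP/DBP among the
covariates (not change scores). Adjustment tiers: model1 unadjusted; model2
adds age, sex, antihypertensive medication, family history, education,
marriage, income (categoricals dummy-coded against the first level) and
baseline SBP/DBP; model3 adds mutual adjustment (lifestyle and GRS groups
together). The 3×3 joint grid is one 8-dummy model per outcome against the
low-GRS / healthful-lifestyle reference cell; empty cells are flagged
sparse rather than fitted.

One covariate required a design decision: by the outcome definition,
medication use at follow-up *implies* incident hypertension, so that
covariate quasi-separates any logistic model of hypertension on a table
satisfying the validation invariant. It is therefore excluded from logistic
hypertension models and retained for the linear BP models.

## Additive interaction (RERI)

Lifestyle is split healthful vs intermediate+unhealthful; GRS at the
cohort median (values at the median count as upper half). With product-term
logistic coefficients (βA, βB, βAB):

RERI = exp(βA+βB+βAB) − exp(βA) − exp(βB) + 1,

odds ratios standing in for risk ratios — a documented approximation, since
incidence here (~19%) is not rare. The default CI is the delta method with
gradient (OR11−OR10, OR11−OR01, OR11); a seeded subject bootstrap is the
cross-check. For continuous outcomes the additive-interaction contrast of
adjusted means equals the product-term coefficient, whose Wald CI is
reported directly.

## Population-impact indicators

With Ie, Iu, It the exposed (lifestyle score 0–3), unexposed (4–5) and
total incidences: RR = Ie/Iu; AR = (Ie−Iu)·100; PAR = It−Iu (reported as a
proportion, matching the source's printed scale, with PAR% = PAR/It·100
alongside); PFP = (Ie−It)/Ie·100, treating the favorable lifestyle as the
protective exposure whose removal would leave the whole population at
incidence Ie; morbidities averted = N·(Ie−It). Indicators are crude (no
adjustment, no CIs, as in the source analysis; a seeded bootstrap exists
but is off by default); display rounding is half-up to 2 decimals, applied
only at output. Per-GRS-stratum columns use the stratum's own totals, and
the pooled morbidities-averted count is reported next to the sum of the
stratum counts (they need not agree exactly).

## Synthetic cohort generator

The generator's defaults are the stated world of the published cohort:
n = 4,592; unhealthful prevalences diet 60.37%, BMI 51.70%, smoking 26.44%,
activity 49.00%, drinking 12.80%; baseline SBP 116.06 ± 11.44 and DBP
73.62 ± 7.59 mmHg; target incidence 18.9%; covariate marginals (age
49.04 ± 11.52, 36.93% men, education/income/marriage/family-history
frequencies) from the published baseline table. Per-SNP allele frequencies
and effect sizes are not published; defaults are illustrative and stated
once: risk-allele frequencies spread over 0.30–0.50 (common variants, as
typical for replicated blood-pressure loci) and modest per-genotype odds
ratios (1.12 heterozygote, 1.25 risk homozygote). Per-factor lifestyle odds
ratios default to modest values (1.05–1.40, adiposity strongest).

Mechanics:

- Genotypes per locus are drawn under Hardy–Weinberg equilibrium; no
  linkage disequilibrium between loci.
- Each factor's unhealthful state is a Bernoulli draw; raw variables are
  then drawn inside the corresponding classification region (CHEI item
  scores composed to an exact target sum on either side of 17; BMI from a
  healthy-band truncated normal or an over/underweight mixture; smoking
  status with quit-years on the correct side of 30; IPAQ level; drinks per
  year). The generator targets the primary BMI rule; re-scoring under the
  sensitivity rule legitimately shifts the realized prevalence.
- Incident hypertension is a Bernoulli draw from a logistic linear
  predictor: per-genotype log-ORs plus per-factor log-ORs
  (`effect_mode=per_factor`, default), or lifestyle-group and GRS-tertile
  dummies at configured group ORs (`effect_mode=group_level`, which makes
  the group contrasts exactly identifiable for parameter-recovery tests).
  The intercept is solved by root-finding so the expected incidence over
  the realized sample equals the target; an unreachable target raises a
  calibration error.
- `interaction_reri_target=0` (default) means no product term — a purely
  multiplicative model, under which the analytic RERI of the dichotomized
  exposures is generally nonzero. A nonzero target calibrates a product
  term against the model-implied dichotomized ORs.
- Baseline BP is truncated below the hypertension cutoffs (the study
  excluded baseline hypertensives); the underlying location is solved so
  the post-truncation mean equals the configured mean, which describes the
  post-exclusion cohort. Follow-up BP = intercept + carry-over from
  baseline + exposure shifts + Gaussian noise. Consistency with the drawn
  outcome is enforced the way treatment would in practice: a case whose
  sampled follow-up BP is below both cutoffs gets the medication flag
  (a treated patient); a non-case above a cutoff is redrawn below it.
- Covariates are independent of the exposures, so analytic expectations
  are checkable; this deliberately omits real-world confounding.

What a green test therefore establishes: the scoring rules, model
machinery, interaction arithmetic and indicator algebra are correct on a
cohort whose generating process is known. It does not establish anything
about questionnaire measurement error, linkage, confounding, loss to
follow-up or secular BP trends — none of which the generator emulates —
and the published adjusted ORs/βs and RERI values, which depend on the
unreleased individual-level data, are not reproduction targets.

## Numerical choices

- Quantiles: NumPy linear-interpolation empirical quantiles; tertile
  boundaries at rank round(n/3) and round(2n/3) of a stable sort.
- Logistic fits: statsmodels IRLS, tolerance 1e-10, max 100 iterations;
  separation is flagged when a coefficient exceeds 30 or its SE exceeds
  100 (and per-SNP effect estimation falls back to 0 with a warning
  instead of failing).
- Rank deficiency is detected before fitting and reported with the
  offending columns.
- All randomness flows from `numpy.random.Generator` instances seeded from
  the configuration; outputs of a fixed (cohort, config, seed) are
  byte-identical.

## Known limitations

- In-sample GRS weights are re-used on the same subjects that produced
  them (as in the source analysis); the resulting optimism is inherited,
  not corrected.
- OR-based RERI overstates risk-scale interaction at ~19% incidence.
- The generator cannot produce missing lifestyle items (subjects with
  missing items are excluded at validation, the assumed handling) and
  draws covariates independently of exposures unless reconfigured.
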