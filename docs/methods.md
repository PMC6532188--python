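# Methods

`densprs` implements the joint analysis of adjusted mammographic density and
a 77-SNP polygenic risk score (PRS) as breast-cancer risk factors, together
with a calibrated synthetic case-control generator that makes every stage of
the analysis testable without access to individual-level consortium data.

## The analysis model

Disease status is modelled by multiplicative (logistic) regression. For a
subject with standardized adjusted density `z_D`, standardized PRS `z_G`,
age, BMI and study membership:

    logit P(case) = b0 + baseline(age, 1/BMI, study) + beta_D z_D + beta_G z_G
                    [+ theta z_D z_G]

The baseline covariates age, 1/BMI and study indicators enter every disease
model. The multiplicative null hypothesis is `theta = 0`: the joint odds
ratio of the two factors is the product of their marginal odds ratios.
Evidence against it is assessed three ways on the same subjects: a 1-df
likelihood-ratio test (LRT) of the product term, a global Hosmer-Lemeshow
calibration test of the no-interaction model, and a tail-based
goodness-of-fit test focused on the extremes of predicted risk, where
screening and prevention decisions concentrate.

### Phenotype construction

* **Adjusted density.** Percent density (PD) and absolute dense area (DA)
  are square-root transformed and residualised by OLS on age, 1/BMI
  (the literal reciprocal, kg^-1 m^2) and study indicators. The adjustment
  model is fitted among controls only and applied to all subjects: controls
  define the reference population, and fitting on everyone would let case
  status shape the residual scale. Residuals are standardized by the control
  standard deviation and cut into quartiles at control quantiles.
* **PRS.** `PRS_i = sum_k beta_k x_ik`, the weighted sum of effect-allele
  dosages over 77 SNPs with published per-allele log odds ratios as weights,
  standardized by the control SD and cut into control quintiles. Quantile
  bins are right-closed; values outside the control range fall into the
  extreme bins, so control counts per bin are equal within +/-1 while case
  counts vary with risk.

### Genotype quality control and imputation

SNP x study blocks failing a Hardy-Weinberg equilibrium (HWE) chi-square
test (1 df, among controls, per study) at P < 0.001 are set to missing, then
missing dosages are imputed by a simple MCMC scheme: each SNP is regressed
on the other SNPs plus age and BMI (coefficients estimated once, from a
single Gram matrix on mean-initialised data), and a Gibbs sampler redraws
every missing entry for 10 burn-in + 20 retained sweeps. Draws are
Binomial(2, mu/2) where mu is the entry's current linear predictor — a
linear-probability conditional whose draws are valid dosages and whose mean
equals the predictor, so under MCAR the mean imputed dosage is unbiased for
2 x MAF. (A truncated-Gaussian conditional was considered and rejected: the
asymmetric truncation biases imputed means by several standard errors at low
MAF.) The imputed value is the mean of retained draws; observed entries are
never modified, and case status is deliberately excluded from the predictors
so imputation cannot leak outcome into the score.

### Inference details

* Logistic fits use IRLS (statsmodels GLM, max 100 iterations, tol 1e-10).
  Separation is flagged when any coefficient exceeds 15 per SD of its
  design column (a scale-invariant reading of "diverging coefficient") or
  when the fitter itself detects perfect prediction.
* Confidence intervals are Wald: exp(coef +/- 1.96 SE).
* The LRT requires bitwise-identical subject sets in both models; a silent
  n-mismatch is rejected as an error.
* Hosmer-Lemeshow: subjects ranked by fitted probability, g = 10 equal-count
  bins (tied probabilities never split across bins; realised bin sizes are
  logged), statistic `sum (O-E)^2 / (E (1 - E/n_bin))`, chi-square with
  (realised bins - 2) df. Bins with expected count < 1 produce a warning but
  the test is still reported.
* Tail-based test: subjects ranked by fitted no-interaction risk; for tail
  fractions {0.01, 0.05, 0.10, 0.20} the standardized deviation
  `z = (O - E)/sqrt(sum p(1-p))` of observed case counts is computed in the
  lower and upper tails (regions under 20 subjects are dropped with a
  warning), and the statistic is max |z|. Its p-value comes from a
  parametric bootstrap: outcomes are regenerated from the fitted null
  probabilities n_null times (default 1000) and the *whole statistic is
  recomputed, including the refit of the null model* — without refitting the
  test is conservative, because fitting shrinks in-sample deviations. One
  master seed spawns a child stream per bootstrap replicate, so any single
  replicate is bit-reproducible. The exact form of a published tail-based
  statistic is not uniquely determined by its description; this
  max-standardized-tail-deviation with a self-calibrating bootstrap null is
  this package's definition, and its type-I error is verified by simulation
  (~4-6% at alpha = 0.05) rather than assumed.
* Study heterogeneity: LRT of factor x study interaction, df = studies - 1,
  with leave-one-study-out support.
* Confounder sensitivity: ORs with and without extra covariates, both fitted
  on the complete-case subset of those covariates so the comparison is like
  for like; the default list is parity, menopausal status and family history
  (hormone-therapy use is tabulated only among postmenopausal women, so
  complete-case adjustment on it would drop every premenopausal subject; it
  can be added explicitly).

## The synthetic generator

The generator emulates the statistical structure of the eight-study
consortium analysis; its defaults are the study conditions, not tuning
knobs.

* **Design.** Eight studies, six population-based, totalling 3628 cases /
  5126 controls (population-based subset 2439/3895). Per-study splits are
  not published and are divided evenly within each group;
  `scaled_config` reallocates proportionally for other totals.
* **Covariates.** Age ~ Normal(62, 8) truncated to [40, 85]; BMI ~
  LogNormal(log 26, 0.15) truncated to [17, 45]. These match the published
  marginal tables (57-61% aged >= 60, ~58% BMI >= 25). Parity, menopausal
  status, family history and HT use are drawn from the published
  case/control margins including their missing-data fractions; they are
  associated with the outcome but independent of density and PRS given
  status (the published sensitivity analysis found them to be
  non-confounders).
* **Genotypes.** 77 independent biallelic SNPs, dosage ~ Binomial(2, MAF)
  (HWE holds). MAFs default to U(0.05, 0.5) and weights to signed
  U(log 1.02, log 1.26) draws fixed by seed: the 77 published per-allele
  odds ratios are cited but not printed, and a weights file is a first-class
  input so published values can be dropped in. No LD is simulated,
  consistent with a sum-of-independent-loci score.
* **Density.** Generated on the square-root scale of the phenotype that
  drives disease (`density_phenotype`, default percent density):
  `sqrt(measure) = intercept + a_age (age-60) + a_inv (1/BMI - 1/26) +
  study_effect + latent`, with study effects ~ Normal(0, 0.5) per seed,
  a_age = -0.03/year, a_inv = 40 (density falls with age, rises with 1/BMI),
  residual SD 1.5. For PD the intercept is 5 (so typical PD ~ 25%) and total
  breast area ~ Normal(175, 40) cm^2 truncated positive gives the dense
  area; for DA the intercept is 6.3 (~40 cm^2) and a truncated-normal
  non-dense area closes the percent. The disease model uses the
  *standardized latent* adjusted density, so generative per-SD log odds
  ratios are directly comparable to pipeline estimates.
* **PRS-density correlation.** The latent is `gamma z_G + eps`. The target
  `rho_prs_density = 0.06` is the published *control-group* correlation;
  case-control selection is a collider that depresses the control
  correlation ~0.014 below the population value at these effect sizes, so
  gamma is solved by root-finding on the (1 - P(case))-weighted population
  correlation rather than the closed-form population identity. The generator
  claims calibration, not mechanism: the true PRS-density link (9 shared
  loci, < 1.5% of density variance) is not modelled.
* **Outcome.** `logit p = b0 + beta_D z_D + beta_G z_G + theta z_D z_G`,
  with the per-SD log odds ratios defaulting to the published estimates
  (OR 1.45 PD / 1.34 DA / 1.52 PRS) and theta = 0. b0 is solved on the
  generated population to hit a prevalence of 0.10 — a design choice, since
  logistic ORs are invariant to outcome-dependent sampling and prevalence
  only determines how large a population must be generated to yield the
  requested cases. Requested case/control counts are drawn per study without
  replacement; an unattainable count raises an error naming the shortfall.
  An `interaction_region = "upper_tail"` mode confines the interaction to
  subjects above the 90th percentile of both factors, for tail-test power
  experiments.
* **Missingness.** 1.1% of dosages are set missing completely at random,
  matching the published genotype bookkeeping.

### What the generator does and does not emulate

It reproduces the first-order statistical structure the analysis assumes:
effect sizes per control SD, the weak PRS-density correlation, HWE, the
age/1-BMI/study structure of density, the case-control design, and
missing-data rates. It does not simulate mammogram reader variability, LD,
population stratification, study-specific measurement platforms, or a
mechanistic PRS-density pathway. Passing tests therefore demonstrate that
the *pipeline* is correct and calibrated under the stated model, not that
the model captures every feature of real consortium data.

## Numerical and degenerate-input choices

* Quantile cutpoints use linearly interpolated control quantiles; identical
  adjacent cutpoints (mass ties) raise a degenerate-cutpoint error.
* Rank-deficient adjustment designs are repaired by pivoted-QR column
  dropping, logged per measure.
* Monomorphic SNPs return HWE p = 1 with a flag (no test possible) and are
  never excluded.
* The joint category grid reports an empty cell as OR = NaN with its zero
  counts rather than dropping the row.
* The LRT statistic is clipped at 0 (IRLS round-off can make a nested
  difference infinitesimally negative); df = 0 returns p = 1.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seed and configuration give
  byte-identical outputs, including the report bundle.

## Replicated studies and problem sizes

`densprs.simstudy` drives the package's calibration experiments: 25
replicates of 20,000 cases / 20,000 controls for per-SD OR recovery (mean
within 0.03 of the generative value for PD, DA and PRS), a single 4x-scaled
cohort (20,504 controls) for correlation calibration (within 0.02 of 0.06),
5 replicates for the multiplicative-closure corner ratios of the 4 x 5 grid
(geometric-mean ratio in [0.9, 1.1] per corner — corner ratios at a single
replicate carry ~7% Monte-Carlo noise, so the closure property is scored on
averaged ratios at the same design), and 500 replicates of 2,000/2,000 for
the type-I error of the interaction LRT, Hosmer-Lemeshow and tail tests
(each 3-7% at alpha = 0.05; the type-I study uses n_null = 250 bootstrap
draws, which resolves p-values to 1/251 — ample for a 5% rejection count —
while the package default remains 1000). These sizes were chosen so each
study's Monte-Carlo error is small relative to the tolerance it checks.

## Known limitations

* The tail-based statistic is this package's own construction (see above);
  published tail-based results from other implementations are comparable in
  spirit, not formula.
* Imputation is single-chain with coefficients frozen at initialisation — a
  deliberate "simple MCMC" reading; it is not a substitute for genotype
  imputation from a reference panel and is validated only for its
  mean-preserving behaviour under MCAR.
* The per-SD PRS odds ratio recovered through the full pipeline sits ~0.01
  below the generative value: posterior-mean imputation of 1.1% of dosages
  removes ~1% of score variance, and control-SD scaling in a case-control
  sample shrinks slightly relative to the population SD. Both mechanisms
  operate in any real analysis of the same design.
* Strand ambiguity and allele harmonisation beyond a direct flip
  (2 - dosage) are out of scope; simulated data are pre-harmonised.
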