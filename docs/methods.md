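# Methods

`casecohort` implements the statistical machinery of a multi-country
case-cohort study of an incident disease in which the exposure of interest is
a multi-locus genetic risk score and the questions are (i) the score's
relative hazard, (ii) whether lifestyle factors modify it, and (iii) what it
means for absolute risk. Everything runs on a bundled synthetic-cohort
generator with known ground truth, so every estimator can be checked for
bias, calibration and oracle agreement.

## The case-cohort design and the Prentice pseudo-likelihood

A case-cohort study measures covariates only on a random sub-cohort drawn at
baseline (here centre-stratified) plus all incident cases. Writing
λ(a | x) = λ₀(a)·exp(xᵀβ) for the hazard at attained age *a*, the Prentice
pseudo-partial-likelihood evaluates, at each distinct failure age, a risk set
consisting of the sub-cohort members whose (entry, exit] interval covers that
age plus the failing individual; a case outside the sub-cohort enters only at
its own failure age. `fit_prentice_cox` realises this by shifting each
outside case's entry time to just below its failure time (half the minimum
gap between distinct event times) and then maximising the ordinary
left-truncated partial likelihood. Two tied outside cases at the same failure
time therefore appear in each other's risk sets, consistent with the Breslow
tie convention. Self–Prentice (outside cases at risk over their full
follow-up) and Barlow (inverse-sampling-fraction weights for sub-cohort
non-cases) schemes are provided for sensitivity analyses.

Estimation is Newton–Raphson with step-halving; a step is only accepted if
the pseudo-likelihood does not decrease. Convergence requires max |gradient|
< 1e-6 and a relative likelihood change < 1e-9, within 50 iterations;
non-convergence is returned as a diagnostic flag, never silently. Constant
columns are detected and pinned to coefficient zero; a singular information
matrix raises an error naming the collinear columns. Ties use the Breslow
approximation by default (the dominant convention in the case-cohort
literature and exactly verifiable against standard software); Efron is
available. Centre enters as indicator covariates by default, with a
stratified-baseline mode (separate baseline hazard per stratum) as an
option.

Variance is the grouped sandwich estimator: per-row Breslow score residuals
are summed within participant, and the robust covariance is
H⁻¹·(Σᵢ UᵢUᵢᵀ)·H⁻¹ with H the observed information. With sub-cohort = cohort
this reproduces `survival::coxph`'s cluster-robust variance to machine
precision (the test suite asserts 1e-6; observed agreement ≈1e-14). The
"jackknife-style" variance often quoted for case-cohort fits is the
infinitesimal jackknife, which is this same dfbeta-based sandwich; no
separate estimator is shipped. Under the Efron option the residuals are
evaluated with the Breslow formula at the Efron estimate — an approximation
that is exact without ties.

## Genetic risk score

Dosages are oriented so that each locus counts its risk allele (flipping
d → 2−d where the stored counted allele is the non-risk allele). Sporadically
missing genotypes are imputed with the mean observed dosage at that locus
among individuals of the same case status — incident cases anywhere in the
analysis set versus everyone else — and only for individuals genotyped at
`min_genotyped` or more loci (default L−2, the generalisation of a 47-of-49
completeness rule); less complete individuals are excluded, not imputed.
The raw score is the (optionally externally log-OR-weighted) dosage sum. The
standardisation mean and SD (sample SD, ddof = 1) and the quartile cutoffs
(25/50/75 percentiles, left-closed right-open intervals with boundary ties
assigned upward) are always computed in the sub-cohort only and then applied
to all rows; with both the mean and SD taken from the sub-cohort, the
configurable reference subset makes other conventions available. The HWE QC
test is the 1-df chi-square goodness of fit against p², 2pq, q² at the
estimated allele frequency; statistics below 1e-12 are reported as exactly 0
(exact-proportion counts), and monomorphic loci are flagged rather than
tested.

## Pooling and meta-regression

Per-country estimates are combined by DerSimonian–Laird method-of-moments
random effects (the era-standard estimator; REML was deliberately not used
so that worked examples are exactly hand-checkable):
w = 1/se², Q = Σw(β−β_FE)², τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)),
then re-weighting by 1/(se²+τ²). I² = max(0, (Q−(k−1))/Q). Meta-regression
on country-level moderators (sub-cohort means of age, BMI, WC) is weighted
least squares with the analogous method-of-moments residual τ²; with an
intercept only it reduces exactly to the random-effects pool. With k ≈ 8
countries, τ² and I² are very noisy — single synthetic cohorts legitimately
produce I² anywhere from 0% to ~70% under modest true slope heterogeneity.

## Interactions and family-wise error

An interaction is estimated by adding a product term to each country-specific
fit and pooling the product-term coefficients; the p-value is the Wald test
on the pooled estimate. Ordered factors (BMI group, WC group, activity) are
coded as equally spaced integers giving a single interaction parameter
(matching the one-parameter-per-test family design); a categorical coding
with per-level product terms is available, whose global p treats the pooled
per-level terms as independent (an approximation, flagged here). Countries
without events or without factor variation are dropped with k reduced; a
factor constant everywhere raises an inestimability error. Baseline-age
interactions must be run on a follow-up-scale analysis set, since age cannot
be both the time scale and a covariate. The default test family is the seven
score-level lifestyle factors (sex, family history, BMI group, WC group,
baseline age, physical activity, diet score), with Bonferroni thresholds
α/m: 0.05/7 ≈ 0.007 and 0.05/343 ≈ 1.46×10⁻⁴.

Stratified HRs refit the exposure within each factor level (per country,
pooled per level); empty or event-free strata are reported as missing rather
than dropped. Age-at-diagnosis analyses censor cases outside the target
diagnosis-age group at their event age; a non-sub-cohort case so censored
contributes to no Prentice risk set and is dropped from that group's fit —
the groups partition the events exactly.

## Absolute risk

Absolute cumulative incidence is estimated on the follow-up time scale
(horizons like "10-year risk" are follow-up durations, not ages). The full
cohort is recreated from the sub-cohort by resampling with replacement,
stratified on (score quartile × factor level): strata receive rows by
deterministic largest-remainder proportional allocation, so reconstruction
proportions match the sub-cohort exactly up to rounding, and draws within a
stratum are uniform with replacement. Within each stratum the incidence is
1 − Ŝ(t) with Ŝ the Kaplan–Meier product-limit estimator (death and
administrative end of follow-up treated as censoring; no competing-risk
correction). The default averages 50 reconstructions and reports the
Monte-Carlo SE of the mean; `replicates=1` reproduces single-resample
behaviour. The spread across reconstructions (√replicates × MC SE) estimates
the sampling error of one sub-cohort-based estimate, which is the scale used
when validating against full-cohort KM on synthetic data.

## The synthetic cohort generator

The generator emulates the design features the estimators depend on, not the
biology of any real cohort:

- **Structure** — 8 countries × 3 centres; entry age N(52, 9.5²) truncated
  to [25, 75]; staggered recruitment over 11.6 y with administrative
  censoring 17.5 y after study start, giving ≈11.7 y mean follow-up.
- **Events on the age scale** — baseline hazard λ·k·(a/ā)^(k−1) (default
  k = 1: constant 3.8 per 1,000 person-years, matching a large European
  incident-diabetes cohort), multiplied by exp(linear predictor); event ages
  are drawn by analytic inversion given left truncation at entry age, so
  delayed entry is a real feature of the data. λ is the hazard at the
  cohort-mean linear predictor: with effects present, Jensen's inequality
  makes the marginal rate somewhat higher (≈4.5–4.8 with defaults).
- **Genotypes** — Hardy–Weinberg binomial(2, p) draws at the bundled 49
  loci. The bundled table's rsIDs, risk alleles and per-allele hazard ratios
  (1.01–1.33) are published values for established T2D loci; the
  risk-allele frequencies and non-risk alleles are synthetic stand-ins
  calibrated once so the unweighted score has mean ≈52 and SD ≈4.4 alleles
  (quartile cutoffs near 49/52/55) — they are labelled synthetic in the data
  file and must not be used as literature frequencies.
- **Covariates** — sex (36% male), BMI N(26.2, 4.3²) with WHO groups at
  25/30, WC regression-linked to BMI and sex with sex-specific cut points
  (94/102 cm men, 80/88 cm women), 4-level activity index, 0–18 diet score,
  family history partially caused by the score (logistic gradient 0.115 per
  score SD, reproducing a ≈15%→19% bottom-to-top-quartile gradient), and a
  lognormal energy-intake ratio for the 1%/99% exclusion filter.
- **Default effect sizes** (log-HR units): BMI group 0.70 (obesity
  dominant), sex 0.25, family history 0.45, activity −0.10, diet −0.03;
  score×BMI-group interaction −0.028 per allele per category, the magnitude
  that reproduces a per-SD HR gradient of ≈1.6/1.5/1.2 across BMI groups;
  per-country random slopes on the per-allele effect (SD 0.02) as the source
  of between-country heterogeneity. Prevalent disease (3.3%) and unknown
  status (0.8%) flags feed the exclusion flow.
- **Reproducibility** — one integer seed feeds named
  `numpy.random.SeedSequence` sub-streams (structure, genotypes, covariates,
  family history, events, flags); identical configs give byte-identical
  tables. Missingness is injected separately, per cell, at configured
  marginal rates.

What the generator does **not** emulate: questionnaire-derived diet scores,
anthropometric measurement error, genotyping batch artefacts, linkage
disequilibrium between loci, non-proportional hazards, or competing
mortality. Passing tests therefore demonstrate the estimators' correctness
under the design (two-phase sampling, left truncation, multi-country
heterogeneity), not robustness to those data pathologies.

## Problem sizes and numerical checks

The validation suite uses sizes chosen to make Monte-Carlo bounds sharp while
staying desk-scale: oracle equivalence at n = 2,000 (tolerance 1e-6 against
lifelines and R survival); parameter recovery and CI coverage at n = 20,000
with a 5% sub-cohort over 200 replicates (mean within 2 MC SE of ln 1.08,
coverage within [93%, 97%]); interaction null calibration over 500
replicates of an 8-country cohort (rejection at α/7 bounded by α);
reconstruction consistency at n = 30,000 against full-cohort KM within 3
bootstrap SDs per stratum. The acceptance script runs the full pipeline at
n = 100,000 with a 5% sub-cohort — large enough that per-stratum incidence
gradients are stable — in a few seconds.

## Interfaces

All tables are tab-delimited text with an `NA` missing sentinel; cohort
tables are validated on read (dosages in {0,1,2,NA}, event in {0,1}) with
errors naming row and column. Result writers fix column formatting (two
decimals for HRs/CIs, scientific notation for p-values) and record a
`.meta.json` sidecar with config hash, seed and library versions, making
outputs byte-reproducible. The package is a library: the `examples/`
scripts, one per pipeline stage, are the command-line face of the package,
and the acceptance script chains the whole pipeline.
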