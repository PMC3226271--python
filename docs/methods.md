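# Methods

This note documents the statistical models implemented in `pgsa`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Setting

The package targets trials in mild cognitive impairment (MCI), a
presymptomatic high-risk stage of Alzheimer's disease.  Two outcomes are
modelled: the modified ADAScog total (0–85, higher = worse; the classic
cognitive subscale plus Delayed Word Recall and Digit Cancellation) as a
month-24 endpoint, and the NP-Batt composite (mean of nine subtest
z-scores standardized against cognitively normal controls, higher =
better) as a 36-month trajectory.  Time is coded as the visit number in
units of 6 months — the schedule is months 0, 6, 12, 18, 24 and 36, so the
month-36 visit has visit number 6 and there is no visit 5.  All slopes are
changes per visit; a per-year slope is twice the per-visit slope.

## Endpoint model

`sqrt(ADAScog at visit 4) = x'β + ε`, `ε ~ N(0, σ²)`.  The square-root
transform addresses the strong right skew of the raw score; it also makes
a constant treatment effect on the transformed scale correspond to a
larger points-difference at higher (worse) scores, which is clinically
sensible.  Candidate main effects are age, gender, years of education, the
binary obesity flag, ApoE4 allele count, modified Hachinski, and baseline
FAQ, MMSE, ADAScog and NP-Batt.

Selection is strict backward elimination by AIC with single-term
deletions, dropping at each step the term whose removal lowers AIC most
(ties broken by term-name order, so runs are deterministic), to a local
minimum.  Each pairwise interaction of the retained main effects is then
tested singly for AIC improvement; accepted interactions are pooled and
the backward pass re-run, with a main effect protected while any retained
interaction contains it.  Fits go through ordinary least squares
(statsmodels); the selection logic is this package's own.

Covariate codings:

* Gender enters as a 0/1 indicator; the reference level is configurable
  (`CodingConfig.gender_reference`) and defaults to male (women = 1).  The
  reference model's artifact stores a positive gender coefficient, i.e.
  worse predicted month-24 ADAScog for women, under this default.
* BMI is split at 25 and 30 kg/m² into three classes; the trajectory model
  uses the two upper-class dummies (BMI-2, BMI-3), while the endpoint
  model uses a single binary obesity flag.  "Obesity" is defined as the
  top class (BMI ≥ 30), consistent with the three-class split; the
  definition is configurable.
* The ApoE4 allele count enters as a numeric 0/1/2 predictor, reflecting
  the empirical finding that two alleles roughly double the effect of one.
* Trail Making B is sign-flipped inside the NP-Batt composite (it is a
  timed test where lower is better) so that higher composite = better
  performance.

## Trajectory model

`y_ij = x_ij'β + b_0i + b_1i t_ij + ε_ij` with
`(b_0i, b_1i) ~ N(0, G)`, `ε_ij ~ N(0, σ_w²)` independent across visits.
Responses are the NP-Batt scores at follow-up visits (visits 1–6); the
baseline score is a covariate, not a response.  The saturated starting
model contains all candidate main effects plus every candidate-by-time
interaction, with random intercepts and slopes.

Selection proceeds in the order: (1) likelihood-ratio test of random
slopes against a random-intercept-only structure (REML, identical fixed
effects on both sides), retained if p < 0.05; the naive χ² reference with
2 df is used, which is conservative at the variance boundary — a 50:50
χ²₁/χ²₂ mixture would be less so, but the random-slope signal in realistic
data is far from the threshold either way.  (2) Backward Wald elimination,
time-interactions first and then main effects, removing the largest
p-value above 0.05 one term at a time and honoring marginality: a main
effect is never removed while a retained interaction contains it (this is
why a non-significant time main effect stays in the model when
time-by-covariate interactions survive).  (3) Pairwise interactions of the
surviving baseline covariates are screened singly (accepted when their
Wald p < 0.05), pooled, and pruned.  Wald tests use the normal reference
distribution; at the cohort sizes involved (hundreds of subjects) the
difference from a t reference is negligible.

Variance components are estimated by REML.  The solver is an exact
profiled REML/ML implementation specialised to the
random-intercept-plus-slope, iid-residual class: subjects are grouped by
visit pattern, each pattern shares one small marginal covariance
`V = Z G Z' + σ_w² I`, and the fixed effects and likelihood are profiled
from per-pattern sufficient statistics.  Optimization is over
(log sd_int, log sd_slope, atanh ρ, log σ_w) with L-BFGS-B and a
Nelder-Mead polish on failure; moment-based starts come from per-subject
OLS lines.  This makes a single fit on thousands of subjects take well
under a second, which the Monte-Carlo power machinery (hundreds of refits)
and the stepwise selection (dozens of refits) rely on.  statsmodels
MixedLM fits the identical model and serves as the independent
cross-check in the test suite; agreement is to ~4 decimals in coefficients
and ~1% in standard errors.

The marginal SD of one observation at visit t is
`sqrt(sd_int² + t² sd_slope² + 2 t ρ sd_int sd_slope + σ_w²)`; with the
packaged reference variance components this runs from 0.311 at baseline to
0.601 at month 36.  (A published narrative figure quotes 0.32–0.51 over
the same window; the implemented formula is the standard marginal
variance, and the small discrepancy at the endpoints is documented rather
than reverse-engineered.)

## Virtual-placebo simulation

One coefficient vector per simulated trial is drawn from `N(β̂, Σ̂)` and
shared by all subjects — parameter uncertainty acts at the trial level, so
simulated subjects within a replicate are correlated through it, which is
the realistic granularity for trial-level inference.  (A per-subject draw
would average parameter uncertainty away across the cohort.)  Per subject,
the endpoint simulator adds sqrt-scale residual noise, floors at 0,
squares, and clips to [0, 85]; the trajectory simulator adds an
(intercept, slope) pair from `G` and per-visit noise.

The packaged reference artifacts carry the published coefficients and
variance components, but only a *diagonal* parameter covariance built from
the printed standard errors — the off-diagonal covariances were never
published.  Independent draws of strongly collinear coefficients (e.g. the
intercept and the MMSE slope) overstate replicate-level mean dispersion
considerably.  Simulation functions therefore accept
`param_uncertainty=False` to use plug-in coefficients; distribution-level
summaries quoted in the tests use that mode where the diagonal
approximation would dominate, and arm-contrast power simulations are
unaffected (a shared draw cancels in the treatment-by-time contrast).

## Power

*Endpoint*: the standard normal-approximation two-sample formula on the
sqrt scale, `Φ(δ/(σ√(2/n)) − z_{1−α/2})` plus the opposite-tail term.
Because randomized treatment is uncorrelated with the baseline covariates,
the general regression-parameter procedure collapses to this two-mean
formula.  α = 0.05 two-sided is the default.  With δ = 0.16, σ = 0.669 and
n = 286 per group this gives 82%.

*Trajectory*: Monte-Carlo.  Per replicate, a control arm and a treated arm
are generated from the fitted model over fresh synthetic cohorts, the
treated arm's slope improved by δ z-units per visit; a mixed model with
arm, time and arm-by-time fixed effects and random intercept/slope is
refit and the arm-by-time Wald test recorded.  Covariate-driven slope
heterogeneity (ApoE4-by-time, ADAScog-by-time, BMI-by-time) is absorbed by
the random-slope variance of the refit model and is what brings the power
at 400/arm for δ = 0.02/visit to ≈ 0.80–0.83 rather than the ≈ 0.91 a
homogeneous-slope calculation would give.  Non-converged inner fits are
excluded; above 5% non-convergence the result carries a reliability
warning.  Results report the binomial Monte-Carlo SE (≈ 0.017 at 500
replicates).

## Synthetic cohort generator

The generator emulates the published MCI cohort's *marginals* (n = 397):
age N(74.2, 7.4) truncated to 55–95; 35.5% women; education N(15.7, 3.0);
BMI N(26.1, 4.0); ApoE4 counts (46.6%, 41.6%, 11.8%); MMSE N(27.0, 1.8)
truncated to the 24–30 inclusion window and rounded; ADAScog N(18.6, 6.3)
on [0, 85]; NP-Batt N(−1.02, 0.66); FAQ and Hachinski as truncated
negative-binomial variables matched to median 2 (range 0–21) and median 1
(range 0–4); CSF Aβ42/T-tau log-normal with median 1.564 (σ_log = 0.6,
chosen so a ~200-draw sample spans roughly 0.23–7.6), present for 50.1% of
subjects, mirroring the lumbar-puncture subsample; 60% on anti-dementia
medication.

Dependence is a Gaussian copula over the continuous/ordinal covariates.
The real cohort's covariate correlations were never published, so the
defaults are assumptions: ADAScog with NP-Batt −0.5, ADAScog with MMSE
−0.3, FAQ with NP-Batt −0.3, all else 0.  The strengths were set so the
encoded quantitative predictors reproduce the weak-collinearity profile
reported for the real cohort (every variance inflation factor below 1.70);
stronger settings (e.g. −0.6 for ADAScog/NP-Batt) push VIFs above 2.
Gender, ApoE4, medication and CSF availability are drawn independently.

What the generator does *not* emulate: the real joint distribution beyond
these pairwise latent correlations, informative dropout (the
`apply_dropout` tool is missing-completely-at-random), site effects,
practice effects, and non-Gaussian tails.  Consequently, tests that pass
on synthetic cohorts demonstrate that the algorithms are correct and
well-calibrated under the stated generating process — not that the fitted
models would transport to a new clinical population.  Quantities that
depend on the covariate joint distribution (simulated score dispersions,
simulation-based power) are therefore checked against loose bands, and
data-dependent published estimates (individual regression coefficients
fitted to the real cohort, its R², its cross-validation error) are covered
by parameter-recovery properties instead of value reproduction.

## Validation toolkit

Cross-validation splits at the subject level (a subject's visits never
straddle folds) into k ≈ equal folds and reports the root-mean-square
prediction error on the model's working scale — sqrt-ADAScog for the
endpoint model, z-units with fixed-effects-only predictions for held-out
subjects in the trajectory model.  RMSE (not mean absolute error, which is
available behind a flag) is the default because it is directly comparable
to a residual SD; for a well-specified endpoint model the CV error
converges to σ.  VIFs are computed as `1/(1−R²_j)` over the quantitative
predictors (continuous covariates plus the allele count; binary dummies
excluded).  Distribution comparisons report the seven-number descriptive
table for each sample, their differences, QQ pairs at plotting positions
`(i − 0.5)/n` of the smaller sample with linear interpolation in the
larger, and the two-sample Kolmogorov–Smirnov distance.

## Numerical notes and limitations

* Cohort CSV round-trips are bit-exact: floats are written in shortest
  repr and parsed with round-trip precision.  The file layout stores the
  baseline ADAScog/NP-Batt in the visit-month-0 row, so a visit-0 outcome
  record that disagrees with the baseline covariates is unrepresentable
  and rejected at write time.
* Degenerate interaction columns in the stepwise scans (e.g. the product
  of mutually exclusive BMI dummies) are detected and skipped.
* The LMM solver flags boundary solutions (slope SD ≈ 0 or |ρ| > 0.995);
  the LRT step, not the flag, decides whether slopes stay in the model.
* Back-transformed means are biased low (Jensen); simulation-based
  summaries are preferred for original-scale means, and the documented
  confidence-interval arithmetic squares the sqrt-scale interval endpoints
  rather than propagating a delta-method variance.
* Problem sizes used by the test suite and the acceptance script —
  parameter recovery at 5,000 (endpoint) and 2,000 (trajectory) subjects,
  500 power replicates at 400 per arm, 10,000-subject dispersion checks —
  were chosen so sampling error is small relative to the tolerances while
  a full run completes in minutes on one core.
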