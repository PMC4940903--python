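# Methods

This note documents the statistical model behind `owratio`, the estimation
choices made where the design was genuinely open, what the synthetic-data
machinery does and does not emulate, and the package's numerical
conventions.

## Outcome: BMI standard-deviation scores

A growth reference supplies, per sex, a grid of ages with the BMI mean
μ(age) and SD σ(age).  The SDS of an observed BMI is
`(bmi − μ)/σ` with μ and σ linearly interpolated on the grid.  This is the
two-parameter (mean/SD) transformation; no skewness (LMS "L") parameter is
used, so references fitted with a Box–Cox power must be converted by the
user before loading.  Ages outside the grid raise an error rather than
extrapolate — growth references are invalid outside their fitting range.

Overweight is `sds > cutoff` with strict inequality, cutoffs 1.19 (boys) and
1.11 (girls) at the four-year examination; because the SDS already adjusts
for exam age, the same cutoffs apply across the 3.6–5.0-year follow-up
window.  Under a reference that renders SDS standard normal these cutoffs
correspond to tail masses Φ̄(1.19) = 11.7 % and Φ̄(1.11) = 13.3 %, a closed
form the test suite checks both analytically and by simulation.  LGA is
birthweight SDS > 2 (strict); SGA children belong to the non-LGA reference
class.

The packaged `standard_normal_reference()` is a synthetic testing reference
(gently declining mean BMI, constant SD); national references are user
input, never bundled.

## Individual-level risk model

Overweight is regressed on categorical predictors by maximum-likelihood
logistic regression (statsmodels' Newton/IRLS).  Reference categories are
the lowest-risk study codings: male, non-LGA, non-smoking, BMI ≤ 25, both
parents post-secondary.  Parental BMI categories are ≤25, >25–30, >30 —
both boundaries resolve downward.  Education is derived from the two
parent-level post-secondary indicators; a missing parent makes the category
missing.

**Backward elimination.**  Starting from all candidates, the predictor with
the largest exclusion p-value is removed while that p-value exceeds 0.10.
Exclusion tests are likelihood-ratio tests of all of a predictor's dummy
terms jointly — with categorical blocks a per-term Wald test would depend on
the dummy coding; a joint Wald alternative is selectable
(`criterion="wald"`).  At each step the model is refit on records complete
for the *currently included* predictors, so the analysis set grows as
predictors leave.  Ties in p-values are broken by candidate order.
Separation is surfaced as an error naming the predictor, never silently
penalized.

**Interaction screening.**  Pairwise interactions among the selected main
effects are tested one at a time by likelihood-ratio; those with p < 0.05
are added jointly.  Interactions whose exposed-by-exposed cell carries
fewer than 5 outcome events, or that are not estimable, are skipped with a
logged note.

## Indirect standardization

For stratum *i* and an adjustment set *A*, overweight rates are computed per
cell of the cross-classification of *A* over the whole analysis population
and applied to the stratum's composition:
`E_i = Σ_cells n_{i,cell} · rate_cell`.  When the rates are computed on the
same subset the expectations are applied to, `Σ E_i = Σ O_i` exactly
(asserted to 1e-9 in the tests).  Rates may optionally be computed on a
larger population than the geo-coded children the ratios are formed on
(`rate_cohort=`), mirroring cohorts where a handful of children cannot be
mapped to a parish.

The *crude* ratio keeps a gender standardization by default
(`adjust_vars=["sex"]`): published per-stratum expected counts in this
study design are consistent with sex-specific rates applied to each
stratum's gender split, not with a single overall rate.  A fully crude mode
(`adjust_vars=[]`) is available.  The *adjusted* ratio standardizes over the
full cross-classification of the backward-selected predictors on their
complete cases.  Sparse cells are left as-is (a cell rate may be 0 or 1);
smoothing happens downstream at stratum level, not at cell level.

Confidence intervals for `O/E` use the exact (Garwood) Poisson limits for
`O` — chi-square quantile form, lower limit 0 at `O = 0` — divided by `E`.
The tests check them against brute-force inversion of the Poisson tails.

## Poisson–Gamma empirical Bayes

Per area, `O_i ~ Poisson(θ_i E_i)`; the ratios are exchangeable with
`θ_i ~ Gamma(α, β)` (shape/rate).  Conjugacy gives
`θ_i | O_i ~ Gamma(O_i + α, E_i + β)`, hence the EB estimate
`(O_i + α)/(E_i + β)`, equal-tailed posterior quantile intervals (the
printed near-symmetric intervals of this literature are credible intervals,
not Wald approximations) and the exceedance summary `P(θ_i < 1)` from the
posterior CDF.  Shrinkage is towards the prior mean, strongest where `E_i`
is small; the posterior mean always lies between the raw ratio and the
prior mean.

Three hyperparameter estimators are provided:

- **`moments` (default).**  Gamma moments matched to the raw ratio ensemble
  `{O_i/E_i}`: prior mean = ensemble mean, prior variance = ensemble sample
  variance (n−1).  No subtraction of the within-area Poisson component.
- **`mle`.**  Marginal (negative-binomial) maximum likelihood on the exact
  marginal `O_i ~ NB(α, β/(β+E_i))`, L-BFGS on log-parameters with an
  analytic gradient and a stationary-point polish; at an interior optimum
  the gradient norm is below 1e-6 (tested).  Parameter recovery is tested
  on simulated 200-area ensembles (unbiased to within 15 % averaged over
  replicates; a single 200-area ensemble carries ~12 % sampling noise).
- **`clayton-kaldor`.**  The classical moment iteration alternating
  posterior means with prior-moment updates that allow for the Poisson
  component of the spread.

The default is deliberate.  With very small ensembles (the motivating
analysis has four strata), estimators that subtract the within-area Poisson
variance routinely find a non-positive between-area variance: on such data
the marginal MLE diverges (α → ∞) and the Clayton–Kaldor iteration
collapses, shrinking every area fully to the ensemble mean and erasing the
signal the analysis exists to measure.  Matching the raw-ratio ensemble
keeps a conservative, strictly positive heterogeneity estimate — it
attributes all observed spread to real between-area variation, i.e. it
*under*-shrinks rather than over-shrinks — and is the convention that
reproduces the published smoothed columns of this study design.  With many
areas and large expected counts the three estimators agree closely (tested);
for ensembles of dozens of areas `mle` is the better-grounded choice and a
one-line switch.  With only four areas, frequentist uncertainty on (α, β)
is not meaningful and is not reported; the surfaced uncertainty is
per-area posterior only.

## Chained-equations imputation

Missing categorical predictors are imputed by fully conditional
specification: initialize by marginal draws, then cycle variable-by-variable
(fixed order), refitting a multinomial logistic model of each variable on
the other predictors, the outcome and the stratum (outcome-aware imputation,
the standard FCS recommendation) and drawing from the fitted conditional
distribution.  Defaults: m = 5 completed datasets, 10 sweeps; parental BMI
is imputed on its categorical analysis scale.  Observed cells are never
altered, and the whole procedure is bit-reproducible given the seed.
Conditional fits use ridge-stabilized multinomial regression (C = 100, i.e.
near-ML with a safeguard against separation in sparse conditionals); a
degenerate conditional falls back to a marginal draw with a logged note.

The sensitivity analysis re-runs standardization + EB per completed dataset
and reports the per-imputation affluent-stratum estimates and their spread.
No Rubin pooling is applied to the EB ratios: the question asked of the
imputation is consistency of the completed-data analyses, not a combined
estimate, and Rubin's rules for a posterior mean of a nonlinear ratio would
suggest precision the four-area model cannot support.

## Synthetic cohorts

`generate(config)` draws cohorts from the model the analysis assumes:
children allocated to strata by size, independent categorical predictors
from configurable marginals, overweight from a logistic model whose
intercept is solved (exact enumeration of the product mixture + Brent root
finding, |prevalence gap| < 1e-4) to hit a target prevalence of 11.9 %, and
per-stratum contextual log-effects (defaults log(0.73), log(1.09),
log(1.01), log(1.13)).  Default effect sizes are the multivariate
(conditional) log odds ratios of the published association table; missing
values are masked MCAR at the published per-predictor rates, with an
education-linked MAR mode for imputation testing.  BMI values are
back-computed from an SDS drawn consistently with the overweight flag, so
the classification stage reproduces the generated outcome exactly.

`fixture_study()` is a quota-built, deterministic 2,026-child emulation of
the published cohort.  Exact by construction: the stratum × gender ×
overweight table (310/746/860/104 geo-coded children plus 6 unmapped; 242
overweight, 108 boys/134 girls; 6.8 % prevalence in the most affluent
stratum), every predictor-category × overweight margin including the
missing-value counts (91/137/329/207), and 23 SGA children, none
overweight.  Joint predictor cells that the printed margins underdetermine
are filled by iterative proportional fitting from a seed that encodes the
multivariate effect structure; the printed per-stratum predictor splits
enter as soft IPF targets after a small 2-D IPF resolves their rounding
inconsistencies with the cohort-wide margins.  Two scalar calibrations are
solved, not hand-tuned: the smoking–confounding tilt (smokers placed
preferentially in high-risk parental cells so that the printed marginal
smoking association arises with *no* conditional smoking effect, matching
its exclusion from the published multivariate model) and a shared
nonresponse correlation (families missing one questionnaire variable tend
to miss others), targeted at the published complete-case count of 1,643
(achieved: 1,636).  The fractional IPF table is integerized by largest
remainder within each stratum × gender × overweight cell, followed by
single-record moves that repair every predictor × overweight margin to the
exact printed integers.

What the fixture does *not* pin down: the true within-stratum joint
distribution of predictors (not printed), so the *adjusted* expected counts
differ somewhat from the published ones (fixture affluent-stratum E ≈ 24
vs 26.6 published) even though the crude (gender-standardized) table
reproduces almost exactly.  Tests of the adjusted chain on the fixture are
therefore qualitative (direction and magnitude class), while exact
reproduction tests use the published (O, E) pairs directly.  The generator
also makes no attempt to emulate longitudinal growth trajectories,
within-parish heterogeneity, or predictor correlations beyond the two
calibrated dependencies; passing tests demonstrate correctness of the
pipeline under these stated conditions, not robustness to every feature of
real registry data.

## Numerical conventions and test scale

- Boundary conventions: overweight/LGA cutoffs strict (">"); BMI category
  boundaries 25 and 30 resolve downward; stratum intervals
  [0, 10), [10, 20), [20, 30), [30, 100] percent.
- Logistic convergence: Newton with tolerance 1e-10 on the objective;
  non-convergence or |coef| > 15 raises a separation error.
- Exact Poisson limits via chi-square quantiles; EB posterior quantiles via
  the Gamma inverse CDF.
- Determinism: every stochastic component takes a seed; same seed, same
  bytes (tested for the generator, the fixture, imputation and the full
  report bundle).
- Simulation-based tests run at deliberately modest scale — 120 replicates
  of n ≈ 2,000 cohorts for CI coverage, 30 MCAR replicates for imputation
  unbiasedness, 25 replicates for effect recovery, 10^5 posterior draws and
  10^6 classification draws for the sampling oracles — sizes chosen so the
  suite completes in well under a minute per file while keeping Monte-Carlo
  error far below the asserted bounds.

## Limitations

- The EB model ignores spatial adjacency (no CAR/BYM smoothing) and fits no
  hyperprior; with four areas the prior is estimated, not known, and the
  credible intervals do not propagate hyperparameter uncertainty.
- Indirect standardization requires every stratum cell to occur in the rate
  population; model-based (continuous-covariate) expected counts are out of
  scope.
- The two-parameter SDS ignores BMI skewness; cutoff-based classification
  is sensitive to reference misspecification in the tail.
- Geo-coding, registry linkage and the computation of parish purchasing
  power are upstream of this package: the parish table is an input.
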