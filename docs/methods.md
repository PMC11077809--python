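# Methods

## The problem

A regional health service that funds its territorial areas from historical
spending perpetuates whatever inequities history contains: an area that has
always spent more keeps receiving more, regardless of whether its population
actually needs more care. A needs-based capitation formula replaces the
historical criterion with an *adjusted population*: each covered person is
weighted by the expected cost of someone with their demographic and
morbidity profile, and the fixed regional budget is split in proportion to
those weights.

`amgcap` implements this analysis end to end for populations stratified by
Adjusted Morbidity Groups (AMGs): a cost GLM on sex, 5-year age band and
AMG; the model-selection and specification battery customary for highly
skewed individual healthcare costs; per-AMG cost weights; and the
three-way budget allocation (by population, by need-adjusted population,
by historical share). Because the person-level data of the motivating
system (the Murcian Health Service, 1,251,108 cost-incurring users in
2017) are not public, a synthetic-population generator calibrated to that
system's published summary statistics stands in for them; every stage is
tested against it.

## Cost model

For individual annual cost \(Y_i > 0\) with covariates \(x_i\)
(female indicator, 17 age-band indicators with band 0 as reference, 30 AMG
indicators with the healthy group as reference), the working model is a
gamma GLM with log link:

\[ \mathbb{E}[Y_i] = \mu_i = \exp(x_i'\beta), \qquad
   \operatorname{Var}[Y_i] = \mu_i^2 / \nu . \]

The full menu crosses families gaussian / poisson / gamma / inverse
gaussian (variance \(\propto \mu^p\), \(p = 0,1,2,3\)) with links identity
/ log / square root. Estimation is IRLS (statsmodels) with convergence
declared on relative deviance change below 1e-8 within 100 iterations.
Two numerical details matter:

* the IRLS runs at fixed scale 1 — point estimates are scale-free, and
  letting the convergence criterion be divided by an estimated Pearson
  scale breaks down on near-exact fits where that scale tends to 0;
* identity and square-root links with gamma or inverse-gaussian variance
  can step outside the mean's domain early in the iteration, so starting
  values come from an OLS fit of the link-transformed response.

Standard errors use the Pearson dispersion (\(X^2/(n-p)\)).
Information criteria use the *maximum-likelihood* dispersion, profiled out
per family (closed form for gaussian and inverse-gaussian, a digamma
root-find for the gamma shape), with the dispersion counted as a
parameter; the poisson family on continuous costs is quasi-likelihood and
gets no dispersion parameter. Both total and per-observation AIC/BIC are
reported.

## Selection battery

* **Information criteria**: all 12 (link, family) fits, AIC/BIC minima
  flagged; failures are recorded per row, never dropped silently.
* **Box-Cox** for the link: \(\hat\lambda\) maximises the profile
  log-likelihood of the transformed response regressed on the *full*
  design (the transform is choosing the link of a regression, so the
  design must be conditioned on). Grid search on \([-2, 2]\) at step
  1e-3, local refinement, profile-likelihood 95% CI from the
  \(\chi^2_1\) cutoff. The recommended link is the nearest of
  \(\lambda \in \{0, 0.5, 1\}\) (log, square root, identity). On gamma
  costs the true \(\lambda\) is not exactly 0 — the log of a gamma
  variate with shape 0.5 is left-skewed, and \(\hat\lambda \approx 0.15\)
  with a very tight CI at n = 50,000 — so the decision rule is the
  nearest-target rule, not "CI contains 0" (which would be unattainable
  for genuinely gamma-distributed costs at any realistic sample size).
* **Modified Park test** for the family: fit gamma/log (the link must be
  right for the test to be valid), form raw-scale residuals
  \(r_i = y_i - \hat\mu_i\), and regress \(\ln r_i^2\) on the linear
  prediction \(\hat\eta_i\) by OLS. The slope estimates the variance
  power \(p\); the 95% CI is HC1 heteroskedasticity-robust; zero
  residuals are dropped with a logged count. The recommendation is the
  family with the nearest integer power.

## Specification and validity battery

All residuals are raw-scale (euros). Auxiliary regressions use HC1 robust
covariance throughout: cost residual variance grows roughly with
\(\mu^2\), and classical OLS covariance is badly wrong here (the Copas
slope test's empirical size at \(n = 5{,}000\) was 0.78 with classical
standard errors and 0.13 with HC1).

* **Pregibon link test**: refit with \(\hat\eta^2\) added; two-sided
  p-value of its coefficient. Degenerate collinear cases (e.g. a
  two-pattern design) return p = 1 with a log note.
* **Modified Hosmer-Lemeshow**: sort by \(\hat\eta\) (stable), form 10
  equal-size groups, regress residuals on group indicators without
  intercept, joint Wald test of zero group means. *Known limitation*:
  applied in-sample, this construction is conservative — the fitted
  score equations already force near-zero weighted residual means across
  covariate patterns, which align with the \(\hat\eta\)-deciles; under
  the true model its rejection rate at \(\alpha = 0.05\) is about
  0.00-0.01 rather than 0.05. It retains power against localized mean
  distortions (a +50% top-decile distortion is rejected essentially
  always).
* **Copas test**: per repetition (default 10), a random half/half split;
  fit on one half, predict the other, regress observed on predicted,
  two-sided test of slope = 1. Slope below 1 signals
  shrinkage/overfitting. The summary p-value is the mean over
  repetitions (the aggregation is a package choice; per-repetition
  slopes and p-values are always reported alongside). Rare indicator
  levels absent or collinear within a training half are dropped for that
  repetition via pivoted QR, with those holdout records predicted at the
  reference level. Holdout RMSE/MAE are averaged over repetitions.
  The slope test's empirical size at gamma shape 0.5 is ~0.13 at nominal
  0.05 — the slope's sampling distribution is heavy-tailed at this
  dispersion — which should be kept in mind when reading borderline
  rejections.
* **Fit metrics**: auxiliary \(R^2\) (squared correlation of observed
  and predicted on the euro scale, so models with different error laws
  are comparable), RMSE, MAE; constant predictions give \(R^2 = 0\) with
  a log note.

## Weights and capitation

Per-AMG **predicted means** are averages of individual predictions within
the group — not predictions at group-mean covariates. This matters:
groups differ in age/sex composition, so the ratio of two group means
deliberately differs from `exp` of the coefficient difference (e.g. the
published 239.45/215.57 = 1.111 versus e^0.095 = 1.100). **Relative
weights** divide by the healthy group's mean (exactly 1.000 for the
base). **Average marginal effects** of an indicator flip it 0→1 for every
record, switching sibling indicators of the same mutually exclusive set
off; this counterfactual-switching computation is asserted equal to
brute-force re-prediction in the tests.

The **need index** of an area is its predicted cross-sectional index on
unit scale: area predicted mean / system predicted mean. Predictions are
first calibrated multiplicatively so the predicted system mean equals the
observed one (a log-link gamma GLM does not guarantee
\(\sum\hat\mu = \sum y\); the factor is logged). The **adjusted
population** is covered population x need index — the need index is
estimated on cost-incurring users but applied to the full covered
population, exactly as the motivating analysis combines them; this
assumes users' relative need profiles transfer to non-users. The
three-way **allocation** of a budget B is by covered-population share,
adjusted-population share, and exogenous historical share; each column
sums to B exactly before rounding. Reporting precision: populations to
whole persons, allocations to whole EUR millions, differences to 2
decimals, need indices to 5 decimals.

The historical shares are an *input*: they come from the accounting
system and are not derivable from the model. The bundled reference table
carries the shares implied by the published allocation table (backed out
from the needs-based column minus the printed differences, normalised).

## Synthetic populations

The generator emulates the calibrating system's structure:

* **AMG mixture**: default shares are the published group sizes over
  1,251,108; 31 groups (healthy; acute, pregnancy, chronic in 1 / 2-3 /
  4+ systems, neoplasm; 5 complexity levels each).
* **Age**: per-AMG truncated normal on [0, 105] with the published
  mean/SD (the published moments are all a distribution can be matched
  to); ages floored to integers. **Sex**: per-AMG Bernoulli with the
  published female share; female = 1, and the default sex coefficient
  (-0.126) attaches to that indicator.
* **Costs**: gamma with mean \(\exp(x'\beta)\) using the published
  gamma/log coefficients as the default truth, and a single global shape
  \(\nu = 0.5\) (within-stratum CV of \(\sqrt 2\), matching strongly
  right-skewed individual costs; the selected model assumes a common
  dispersion). Costs are strictly positive by construction — the
  analytic table records only users who incurred expenses.
* **Areas**: nine areas sized like the published covered populations.
  Each area re-weights the AMG shares multiplicatively (default: a
  complexity-graded tilt calibrated to spread need indices like the
  published ones) and may distort realised costs by a multiplier
  (default: the published observed/predicted cost ratios), creating
  over- and under-funded areas for the allocation analysis to expose.
  A per-area `coverage_inflation` (default 1.208, the published covered
  over analytic population ratio) maps analytic users to covered
  population; how zero-cost insured persons relate to users is not
  observable, so this is an explicit dial rather than a guess.

What the generator does **not** emulate: within-stratum age-cost
gradients (costs depend on age only through the band coefficients),
household or provider clustering, zero-cost covered persons in the
person-level table, per-group dispersion differences (a single global
\(\nu\); the published per-group SDs could calibrate per-group shapes
but do not by default), and any secular/seasonal structure. Passing
tests therefore demonstrate correctness of the estimators and arithmetic
under the assumed data-generating process, not robustness to real-data
features outside it.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to make their statistical
tolerances meaningful: parameter-recovery coverage uses 50 replicates at
n = 20,000 on a reduced design (sex + 6 AMG levels + 4 age bands);
selection calibration uses one n = 50,000 default population; test-size
studies use 100 replicates at n = 5,000 on the reduced design. The
pipeline default of n = 50,000 persons is a scaled-down stand-in for the
1.25M-person system; all capitation arithmetic on published aggregates
is exact and independent of simulation size.

## Reproducibility

A single master seed expands into per-stage seeds via `SeedSequence`
spawning in a fixed order; each artifact is stamped with the seed, a
configuration hash and the package version. Identical configuration and
seed give byte-identical output tables.
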