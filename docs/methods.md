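# Methods

This note documents the models implemented in `avypop`, the assumptions
behind them, and the numerical and design choices that were genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Survival versus population-level avalanche mortality

Known-fate data — one Bernoulli outcome per marked animal per year, no
detection uncertainty — are modeled as

    y_it ~ Bernoulli(S_it),
    logit S_it = β0 + offset(stage_it) + β_avy · m_t + u_i,
    u_i ~ N(0, σ²),

where `m_t` is the proportion of the *whole population* killed by
avalanches in year `t` (a population-level covariate entered as a
proportion: 0.07, not 7), stages are the seven sex-age categories with old
males as reference, and `u_i` is an individual random intercept. A single
shared slope is used across stages; the source analysis found sample size
insufficient to estimate stage × slope interactions, and we keep that
restriction.

**Fitting.** The marginal likelihood is maximized directly: the per-group
integral over `u_i` is evaluated with 25-node Gauss–Hermite quadrature
(probabilists' nodes), the 9-parameter objective is minimized with BFGS
(L-BFGS-B polish when BFGS stalls on numeric-gradient precision loss), and
the coefficient covariance is the inverse of a central-difference Hessian
at the optimum. Non-adaptive quadrature is adequate here because the
random-intercept SD in known-fate survival data is modest (σ ≲ 2 logits);
25 nodes integrate the group likelihoods far below optimizer tolerance.
One test cross-validates the fitter against `lme4::glmer` (Laplace) on the
same data: fixed effects agree to < 0.1 logits, σ to < 0.1.

*Degenerate designs.* A stage dummy whose animal-years contain no deaths
(or no survivors) has a likelihood that is flat in its coefficient; as in
lme4, the estimate drifts large with a correspondingly huge SE and a
warning, while the other coefficients are unaffected. Whole-model
separation (a coefficient whose *scaled* contribution |β·max|x|| exceeds
15 logits outside such flagged columns) raises a fitting error with the
offending columns in the message.

**Predictions** condition on the median individual (u = 0), the standard
"typical subject" convention for mixed models; this reproduces the
published stage survivals from the fixed effects alone. The
**proportional survival change factor** is the ratio of predicted survival
at a scenario rate to survival at the mean rate (0.07): identically 1 at
the mean, monotone decreasing in `m` for a negative slope, and satisfying
`S(m) = S(m̄) · Ŝ_change(m)` to machine precision by construction.

**Neonates** are not radio-marked, so their intercept cannot be estimated.
A neonate logit line reuses the fitted slope with intercept solved so that
first-year survival at the mean rate equals a configured baseline
`S_neo` (`logit(S_neo) − β_avy · m̄`). `S_neo` defaults to 0.65, a
mid-range value for coastal mountain goat kid survival in the literature;
because fecundity is calibrated (below), only the neonate *change factor*
— not `S_neo` itself — influences the scenario results.

## Projection model

State vector: female ages 0–19 stacked over male ages 0–19 (40 classes),
censused once per year. Recruitment entries fold the offspring's entire
first year into the fertility terms,

    F[(sex,0), (female,a)] = fecundity(a) · S_neo · sex_share,

so class 0 holds recruits that have already survived their neonate year
and the age-0 sub-diagonal uses the *yearling* survival line — first-year
survival is counted exactly once. The alternative (neonate survival on the
age-0 sub-diagonal and mother's survival in the fertility term) is
algebraically equivalent after calibration; this form was chosen because
it makes the neonate change factor act where first-year survival lives, on
the fertility row. Survival is constant within a stage's age range
(neonate 0, yearling 1, subadult 2, young adult 3–5, adult 6–8, old 9–19,
sex-specific from adulthood; boundaries configurable). The terminal age
class does not survive further. Births are driven by female fecundity
only, with birth sex ratio 0.5; both sexes count toward N.

**Fecundity calibration.** Age-specific fecundities are not published for
this system. A relative shape (first reproduction at 4, ramp at 4–5,
plateau 6–9, senescent decline after 10) is scaled by a single scalar,
found by Brent's method, so that the deterministic dominant eigenvalue at
the mean avalanche rate equals the observed baseline λ = 1.015
(tolerance 1e-6). λ is monotone in the scalar, and the survival-only
matrix (λ = 0 under age truncation) bounds the problem below. Only the
calibrated product fecundity × S_neo matters downstream.

## Scenario simulation

A scenario fixes `m` and applies it every year. Each replicate starts with
100 animals placed on the stable sex-age distribution of the baseline
matrix (largest-remainder rounding to integers), rescales the survival
entries by their stage's change factor (clipped to [0, 1]; over the
calibration range m ∈ [0, 0.3] the clip never engages, which is itself a
tested invariant) and the fertility row by the neonate factor, then
projects 2 or 30 years with an i.i.d. lognormal fecundity multiplier per
year (arithmetic mean 1, SD 0.106 — the observed interannual SD of
natural-scale fecundity estimates, hence the moment-matched
parameterization). The replicate growth rate is the geometric mean
`(N_T/N_0)^(1/T)`; summaries are the replicate mean and 25th/75th
percentiles (numpy linear interpolation). Percentile bands are narrower at
30 years than at 2 years because the mean of 30 i.i.d. log-multipliers has
smaller variance — the same pattern the source study reports.

**What is, and is not, sampled.** By default the change factors and
baseline survivals enter at their point estimates and replicate-to-
replicate variation is environmental (fecundity) only. This is a
deliberate design choice: the published replicate quartile bands are
quantitatively explained by the fecundity noise alone (e.g. a 30-year
band of ±0.003 around λ = 1.015), which implies the original study's
coefficient sampling — drawn from its separate long-term survival model,
whose error distribution is not available — contributed negligibly, and
the avalanche-submodel coefficient SEs are far too large to stand in for
it (sampling them shifts mean λ down by ~0.01–0.015 through the
concavity of the inverse logit and widens the bands an order of
magnitude). `ScenarioSpec(sample_coefficients=True)` enables full
parameter-uncertainty propagation — one multivariate-normal coefficient
draw per replicate from the fit's covariance, held fixed within the
replicate, with survivals and change factors rebuilt from the draw — and
is the right mode for sensitivity analyses with a covariance estimated
from data. The published coefficient table prints SEs but no covariance,
so the bundled `reference_fit()` carries a diagonal covariance; fits
produced by `fit_survival_model` carry the full observed-information
matrix.

**Decline threshold.** The avalanche rate at which half of 30-year
replicates end below their starting size is found by bisection on `m`
with common random numbers (the same replicate seeds at every trial `m`),
which makes the estimated decline probability monotone in `m` and the
search stable; the final bracket half-width is 3e-4 on `m`, and the
decline probability at the returned threshold is reported with a Wilson
95% interval.

## Recovery and recurrence

Recovery time is the closed form `t = log(1/(1−d)) / log(λ_rec)` with
λ_rec = 1.015 (growth observed under average conditions), with a band at
the 25th/75th percentile growth rates (1.012, 1.018). It requires
λ_rec > 1 and d < 1; d = 0 returns 0.

Event frequency is summarized with the simple empirical estimator:
exceedance probability = (#years ≥ threshold)/n, recurrence interval =
its reciprocal. No extreme-value distribution is fitted; a threshold above
the observed maximum is reported at the record's resolution (1/n) and
flagged extrapolated. The bundled 43-year event series fixes the order
statistics that the recurrence analyses quote (single maximum 0.23,
third-largest 0.19, sixth-largest 0.16, at least one avalanche-free year,
mean 0.07); the remaining years are a right-skewed beta-law body. The
stochastic generator `generate_event_series("reference_like")` produces
series with the same gross shape for testing.

Three generation-anchored scenarios (generation time 7.2 years,
configurable):

1. *worst case* — the maximum observed event;
2. *once in a generation* — the k-th largest event with
   k = round(n / generation time), i.e. the magnitude exceeded on average
   once per generation (for n = 43, T = 7.2 this is the 6th largest;
   rounding rather than flooring keeps the conventional reading of a
   7.17 ≈ 7.2-year return event);
3. *generational recovery* — the event whose decline takes exactly one
   generation to recover at λ_rec, solved by root-finding on the
   deterministic decline curve.

Scenario declines are defined as one winter's proportional loss,
`d(m) = 1 − λ̄(m)` from the 2-year (single-event) scenario run.

## Synthetic monitoring data

The generator emulates a staggered-entry known-fate program: individuals
are marked at a stage drawn from a configurable mix (default skewed toward
adult females, as capture programs target reproductive females), at a
uniform age within the stage and a uniform entry year, then followed until
death or study end, aging through stages. Yearly survival follows the
logit-linear truth; a death in year `t` is labeled an avalanche death with
probability `m_t / (expected population-level mortality at m_t)`, so the
expected proportion of the population dying by avalanche equals `m_t`.
Yearly rates default to a draw from the reference-like event distribution.
All generators are pure functions of (parameters, seed); avalanche rates
are stored at 1e-6 resolution so plain-decimal CSVs round-trip exactly.

What the generator does *not* emulate: spatial structure and multiple
study areas, capture/handling effects, cause-of-death misclassification,
year random effects (exposed as future structure but off — the source
model treated only individual identity as random), and autocorrelated
avalanche regimes. Passing tests therefore demonstrate statistical
correctness of the estimators under the assumed data-generating process,
not robustness to these real-data complications.

## Problem sizes and numerics

Test-suite simulations are scaled for a single CPU: 200–1000 replicates
per scenario (Monte-Carlo SE on mean λ ≤ 3e-4, far inside the comparison
tolerances), 20 replicate fits of ~1400 animal-years each for the
parameter-recovery check, and 500-replicate threshold searches. The
acceptance script uses the full 1000-replicate protocol. Eigenpairs come
from `numpy.linalg.eig` with an explicit residual check (‖Av − λv‖ ≤
1e-8); calibration and root-finding use `scipy.optimize.brentq`.

## Known limitations

- No density dependence, immigration, harvest, or climate covariates; the
  projection holds study-average conditions apart from avalanche effects.
- The recovery closed form assumes constant geometric growth during
  recovery; it is exact only in that idealization.
- Wald intervals from the observed information can undercover for
  replicates whose avalanche-rate variation happens to be small (the
  slope is then weakly identified); the recovery test's ≥ 90% coverage
  criterion reflects this.
- The two-sex model is female-dominant; male abundance affects reported
  total-N growth only through transients.
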