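# Methods

## The question and the design

The package implements a Bayesian interrupted time series (ITS) analysis
of psychological distress — the 12-item General Health Questionnaire
(GHQ-12), Likert-scored 0–36 — across three immigration-policy exposure
periods in the UK, comparing five minoritised ethnic groups against a
White reference group. The study window, Aug 1 2009 to Mar 23 2020 (the
first COVID-19 lockdown), is partitioned by two interruptions:

| period | interval | event |
|---|---|---|
| 1 | 2009-08-01 – 2014-05-13 | before the Immigration Act 2014 |
| 2 | 2014-05-14 – 2017-11-27 | Act in force, before mass media coverage |
| 3 | 2017-11-28 – 2020-03-23 | after media coverage of the Windrush scandal began |

Interviews are assigned to periods by their exact date (survey waves span
24 months and can straddle a boundary, so wave numbers are descriptive
only). Because the underlying panel (UKHLS, special-licence access) is
not redistributable, the package ships a synthetic cohort generator with
known ground truth; every inferential property is demonstrated on
generated data, and the published effect sizes are used only as planted
defaults, not as validation targets.

## The model

For analysis row *i* (one person-interview) with covariate vector
x_i, calendar year y(i) and local-authority area a(i):

    GHQ_i ~ Normal( x_i' β + u_{y(i)} + v_{a(i)} ,  σ² / w_i )
    u_j ~ Normal(0, τ_year²)        v_k ~ Normal(0, τ_area²)

The fixed-effect vector contains an intercept; indicators for the five
non-reference ethnic groups and for periods 2 and 3; their products (the
ethnicity × period *level* contrasts — the mean differences, MD, of
interest); linear calendar time in years; time since the start of the
row's current exposure period (a clock that restarts at each period
boundary, in years); ethnicity × time-since-period products (the *slope*
contrasts); and dummy-coded confounders (sex, age, urban dwelling,
relationship status, number of children, education, health impairment,
housing status, deprivation decile, employment status, UK-born, income
band). With six ethnic groups and three periods the interaction block is
10 level columns and 5 slope columns.

Two coding choices are configurable:

- `period_coding` — `"vs-baseline"` (default) contrasts both period 2
  and period 3 against period 1, so the period-3 MD is the cumulative
  change since the pre-Act era (consistent with reading the period-3
  estimate as a further increase over period 2); `"sequential"` codes
  period 3 as the increment over period 2.
- `slope_interactions` — `"shared"` (default) uses the single resetting
  time-since-period clock and one slope contrast per ethnicity;
  `"by-period"` splits the clock by period and estimates separate slope
  contrasts for periods 2 and 3. Under the shared coding the effect
  table shows the same slope contrast in both period columns. The exact
  linear predictor of the original analysis is not public; the default
  layout is the minimal structure consistent with the published table
  shapes and is flagged here as a reconstruction.

Note a structural fact of the default layout: because the within-period
clock restarts in *every* period (including period 1), calendar time is
an exact linear combination of the clock, the intercept and the period
indicators. The design matrix is therefore rank-deficient by one; the
builder reports this. All ethnicity × period and ethnicity × slope
contrasts are orthogonal to the null direction and remain estimable;
the flat direction among the main time terms is resolved by the
coefficient prior.

### Priors

"Weakly informative" is concretised as Normal(0, 10²) on every fixed
coefficient (GHQ points; `coef_prior_scale=None` gives a flat prior) and
half-Normal(0, 5²) on the three standard deviations (residual, year,
area). All scales are configuration-exposed. An optional person-level
random intercept exists but defaults off: the modelled structure lists
only year and area effects.

### Weights

Attrition weights are the reciprocal of the empirical response
proportion in each (sampling stratum × exposure period) cell, computed
on the included cohort (persons with at least one complete GHQ-12
outcome). They satisfy the Horvitz–Thompson identity exactly: within a
cell, responders' weights sum to the eligible count. The weights enter
the Gaussian likelihood as precision multipliers, σ²/w_i — the standard
Bayesian analogue of weighted least squares. For the location parameters
this is identical to multiplying each row's log-likelihood contribution
by w_i, and it has the convenient exact property that a globally
rescaled weight vector cancels from the coefficient posterior. It is a
pseudo-likelihood: interval calibration under strongly variable weights
is approximate, which is one reason the unweighted sensitivity analysis
exists. No trimming or model smoothing of the response probabilities is
done; a person-level response model is a documented alternative reading
of the weighting description that is deliberately not implemented.

### Inference engine

The posterior is sampled by a collapsed blocked Gibbs sampler written in
this package (the contract is "any engine that yields the posterior of
this model"; nothing here approximates or reimplements INLA):

1. (σ, τ_year, τ_area) are updated one at a time by slice sampling on
   the log scale under the *marginal* posterior with the coefficient and
   random-effect vector integrated out analytically. Collapsing removes
   the funnel that traps a variance component near zero when it is
   updated conditional on its own effects.
2. The joint vector (β, u, v) is then drawn exactly from its Gaussian
   full conditional using a dense Cholesky factorisation of the
   (p + J + K)-dimensional precision matrix built from precomputed
   weighted cross-products — so per-iteration cost is independent of the
   number of rows.
3. The optional person intercept block, when enabled, is updated
   conditionally with O(n) work per sweep.

Slice widths are tuned during warmup (a slice sampler is valid for any
fixed width; tuning only reduces density evaluations) and frozen at the
first kept draw. Default: 2 chains × (250 warmup + 500 kept) sweeps.

Posterior means of coefficients and random effects are
Rao-Blackwellised — averages of the conditional Gaussian means — so
under a flat prior with no random effects the reported posterior mean
equals the weighted-least-squares solution exactly rather than up to
Monte-Carlo error; SDs and the 2.5/50/97.5% quantiles come from the raw
draws. Convergence is assessed with rank-normalised split R-hat (< 1.05)
and bulk effective sample size (> 100) via ArviZ; failing runs are
flagged `converged=False` with a warning, never silently returned. A
tiny diagonal jitter (1e-9 × the largest cross-product diagonal)
stabilises the Cholesky in the rank-deficient and noise-free corners.

## Missing covariates

Covariate missingness (all imputable covariates are categorical) is
handled by chained-equations multiple imputation: missing cells are
initialised from observed marginals, then each incomplete variable is
regressed on all other covariates (plus ethnicity, sex, age, period and
the outcome) with a ridge-stabilised multinomial logistic model and its
missing cells redrawn from the fitted conditional; ten sweeps per
imputed dataset by default. "Ten iterations" is read as chain sweeps;
the number of imputed datasets defaults to the conventional five — both
knobs are exposed.

Pooling is deliberately non-standard and matches the analysed procedure:
instead of Rubin's rules, the five completed datasets collapse into one
pooled dataset whose imputed cells take the most frequent category
across imputations (ties to the lowest category code), and *all*
analyses run on that single dataset. This understates covariate
uncertainty; it is reproduced because it is the procedure under study,
and Rubin's-rules combination is an explicit non-goal. Per-cell
provenance (observed vs imputed) is recorded in one boolean column per
covariate. The outcome, sex and year of birth are never imputed.

## The synthetic cohort generator

One draw produces a person table (ethnicity from the published
composition — 78.9 / 4.34 / 3.78 / 5.43 / 4.82 / 2.73% for White, Black
African, Black Caribbean, Indian, Pakistani, Bangladeshi — sampling
stratum, area, sex, birth year, UK-born with per-group probabilities,
and categorical confounders from simple marginal multinomials) and an
observation table over eleven 24-month wave windows starting Aug 2009,
each shifted 12 months so adjacent waves overlap. Each person-wave
responds with probability `response_prob[stratum, period]`
(defaults 0.70–0.90 by stratum, declining ×0.90 / ×0.85 in periods 2/3);
responders get an interview date uniform in the window.

The latent outcome mean mirrors the fitted model exactly: group baseline
(defaults 11.1 / 10.3 / 11.4 / 10.9 / 11.9 / 11.7 GHQ points) + secular
trend × calendar years + level effect(ethnicity, period) + slope
effect(ethnicity, period) × years since period start + year effect +
area effect. Gaussian noise with SD `sigma_resid` (default 5.4, the
White-group baseline SD) is added, the total is rounded and clamped to
[0, 36], and the integer total is split greedily into twelve item scores
(fill items to 3 in index order) whose sum always reproduces it — the
item layer exists only to exercise the scorer. Per-group baseline SDs
are retained as calibration targets and drive an optional
heteroscedastic mode; the homoscedastic default keeps the generator
exactly matched to the model likelihood. Planted defaults: Black
Caribbean level effects +0.67 (period 2) and +1.28 (period 3), all other
level effects, all slope effects and the secular trend 0 — so the
default generator is simultaneously calibrated to the published baseline
table and correctly specified for the fitted model. Every planted
parameter, including the realised year/area effects and the clamp
fraction, is written to a flat truth map (YAML sidecar).

Covariate missingness is injected afterwards: each maskable covariate
cell is masked independently with probability 0.13 (GHQ items, sex and
birth year are never masked — their absence is an eligibility matter).

### What the generator does *not* emulate

Household clustering; the panel's official design weights; the joint
distribution of confounders with ethnicity (marginals only, so
confounder-driven confounding is absent and confounder coefficients are
truly zero); informative (outcome-dependent) non-response — response
varies only by stratum and period; and person-level outcome correlation
(no person random intercept in the default process, matching the
modelled structure). Passing tests therefore demonstrate correctness of
the machinery and calibration of the inference under the stated process,
not robustness to the richer dependence structure of real panel data.
Note also that independent per-cell masking compounds across a person's
~7 interviews × 10 covariates, so at the default 13% cell rate almost
every person has *some* missing cell; complete-case sensitivity analyses
are exercised in tests at lower masking rates.

## Numerical and procedural choices

- Year length 365.25 days for all time covariates.
- Age = interview year − birth year (year-of-birth granularity).
- Eligibility filters run in a fixed order (out-of-window interviews;
  under-16 at interview; incomplete GHQ-12 outcomes, then persons with
  none left; missing sex/birth year; out-of-scope ethnicity) so the
  exclusion log is deterministic; filters are idempotent.
- Period date intervals are closed on both ends, exactly as printed.
- A person interviewed twice within one period contributes both rows.
- Income stratification dichotomises the ordinal income band at the
  cohort median, the exact-median band going to the lower stratum.
- Mode-pooling ties break to the lowest category code.
- All randomness flows from user-supplied integer seeds through
  numpy SeedSequence spawning; rows are canonically sorted by person and
  date before any seeded draw, so input row order cannot change results.

## Problem sizes used in the checks

Simulation-based checks run at desk scale, chosen once as the package's
own defaults: interval coverage uses 60 replicates of 1 200-person
cohorts in the test suite and 200 replicates of 2 000-person cohorts in
the acceptance script (binomial Monte-Carlo error ≈ 1.5–3 percentage
points); bias recovery uses 100 replicates at n = 5 000; generator
calibration uses one 50 000-person cohort; the noiseless-recovery check
is a single exact run. Coverage and recovery replicates disable
covariate masking so the data-generating process matches the model
likelihood exactly (mode-pooled imputation is a procedure, not part of
the probability model).

## Known limitations

- Mode pooling before analysis ignores between-imputation variance by
  construction (faithful to the procedure under study).
- Precision-multiplier weighting is a pseudo-likelihood; intervals are
  exactly calibrated only when weights are uninformative.
- Random effects are iid Gaussian; first-order random-walk (year) and
  spatially structured (area) alternatives are out of scope.
- The published effect estimates themselves cannot be reproduced without
  the licence-restricted panel; nothing in this package claims to.
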