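# Methods

## The analysis problem

`diaryreact` implements a Bayesian pipeline for intensive-longitudinal
(daily-diary) data in which repeated evening surveys are nested within
persons.  The scientific question it targets is whether *awareness of
age-related change* (AARC) — a person's daily perception of the gains and
losses attributable to their own aging — moderates affective reactivity to
daily stressors in middle-aged and older adults.  The outcomes are daily
negative affect (1–5 item-mean scale), subjective vitality (1–7), and
affect balance; the key predictors are daily stressor severity (a 0–25 sum
of severity ratings over five stressor categories) and the AARC-gains and
AARC-losses subscale scores (5–25 sums of five items each).

## Model

For person *j* on day *i*, with a latent outcome on the standardized scale,

    y*_ij = x_ij' β + u_j + ε_ij,        u_j ~ Normal(0, τ)

and the observed score is y*_ij censored at the scale bounds.  Negative
affect uses a left-censored **skew-normal** residual (the scale floor is
heavily occupied and residuals are right-skewed); vitality uses a
left-and-right censored **normal** residual.  The skew normal is
*mean-parameterized*: μ, σ and the shape α are the distribution's mean, SD
and skewness parameter, so regression coefficients act on the outcome mean
through an identity link.  Internally (ξ, ω, α) location-scale parameters
are used, with CDF Φ(z) − 2·T(z, α) (Owen's T); both T partials have closed
forms, which gives exact analytic gradients for the censored likelihood.

The predictor matrix follows the usual between/within disaggregation for
diary data: each time-varying predictor (stress severity, AARC gains,
AARC losses) is standardized on the pooled long-form sample and split into
a person-mean (BP) column and occasion-deviation (WP) column, so BP + WP
reconstructs the standardized variable exactly.  Interaction products
(two-way WP products and the three-way WP gains × WP losses × WP stress
term) are formed from the standardized WP columns and not re-standardized.
Binary predictors are coded −1/+1; study day (0–9) enters linearly and
quadratically, both standardized; continuous covariates (age, physical
functioning) are standardized long-form.  Occasions with any missing model
variable are dropped listwise (per occasion, not per person).

Priors are weakly informative: Normal(0, 1) on the intercept and every
coefficient, half-t(df = 3, scale = 2.5) on the residual SD σ and the
random-intercept SD τ, and Normal(0, 4) on the skew-normal shape α.

### Vitality censoring bounds

The vitality scale runs 1–7 and its observed range spans the full scale, so
the default design censors at (1, 7).  A literal (1, 5) variant can be
requested via `vitality_design(vitality_bounds=(1, 5))` for comparison with
analyses that censored at those values; it is not the default because a
bound inside the observed support would misclassify valid responses.
Negative affect is modeled as left-censored only: its ceiling is far above
the bulk of the data, and values at the ceiling (rare in simulation, absent
in the observed-range description of the instrument) are treated as exact.

## Sampling

No general-purpose gradient-based PPL is part of this package's
dependency footprint; the sampler is a self-contained no-U-turn HMC
(recursive multinomial variant) with dual-averaging step-size adaptation
(target acceptance 0.8) and a mass matrix estimated from warmup in two
refinement rounds.  The metric is dense by default: the person-level
coefficients are posterior-correlated with the random intercepts, and a
diagonal metric leaves that collective direction slow (bulk ESS per draw
roughly 5–10% versus ~40% dense).  Estimated correlations are shrunk
toward zero by a factor n/(n + dim/2 + 5) while the warmup window is short
relative to the dimension, keeping the metric well-conditioned; a diagonal
variant remains available (`SamplerConfig(metric="diag")`).  Divergent
trajectories (energy error > 1000) are rejected and counted.  Person intercepts are parameterized **centered** by
default — each person contributes ~8 informative occasions, which makes the
centered geometry well-conditioned — with a non-centered option
(`u_j = τ z_j`) for sparse-data settings.  σ and τ are sampled on the log
scale with Jacobian terms.  Defaults are 4 chains × (1000 warmup + 1000
draws); `fit()` raises a convergence error naming the offending parameters
unless every reported parameter has split R-hat ≤ 1.01 and bulk ESS ≥ 400
(thresholds are configurable in `SamplerConfig`, and reduced-size runs used
in examples and tests say so explicitly).

The intercept-only variance-components model (used for the ICC / variance
decomposition of the AARC subscales) is uncensored and Gaussian, so the
person intercepts are marginalized analytically (compound-symmetry marginal
likelihood per person) and the remaining 3-parameter posterior (μ, log σ,
log τ) is sampled with an affine-invariant ensemble sampler.  The reported
within-person share is the posterior mean of 100·σ²/(σ² + τ²).

## Inference: HDI + dual ROPE

Each substantive coefficient is summarized by its posterior mean (Est),
SD (Error), and the 95% highest-density interval computed by exhaustive
search over sorted-draw windows on the pooled post-warmup draws.  Decisions
compare the HDI with a region of practical equivalence around zero: ±0.05
for main effects and, for interaction terms, both ±0.05 and a less
conservative ±0.025.  HDI entirely outside the ROPE supports the
alternative; entirely inside supports the null; otherwise undecided.
`P_meaningful` is the posterior mass beyond the ROPE on the side of the
posterior median (the median sign operationalizes "the observed
direction"); `P_null` is the mass inside the ROPE.  Proportions are
computed from raw draw counts and rounded only at presentation.  If the
draw density inside the HDI dips below 5% of its peak the interval is
flagged as potentially multimodal rather than silently reported.

## Interaction probing

The stress-reactivity slope at WP-gains offset *g* and WP-losses offset *l*
is computed per posterior draw as
`β_s + β_gs·g + β_ls·l + β_gls·g·l`.  "±1 SD" offsets default to the
empirical SD of the standardized WP component columns (which is below 1,
because a WP column is one component of a long-form-standardized variable);
`unit="one"` uses ±1 on the standardized scale instead.  The
difference-of-differences of the four ±1 SD cells is oriented so that it
equals `4·sd_g·sd_l·β_gls` draw-by-draw — the effect size of the three-way
interaction.  Quadratic-stress probes evaluate the partial linear predictor
over a WP-stress grid at fixed WP-losses levels with HDI bands.

## Model comparison

Expected log pointwise predictive density is estimated by PSIS-LOO:
importance ratios 1/p(y_i|θ^s) per observation, tail-smoothed by a
generalized-Pareto fit (the Pareto-smoothing step uses `arviz.psislw`);
pointwise elpd is the log smoothed-weighted mean likelihood, the SE of a
total or difference is √(n·var(pointwise)), and observations with Pareto
k̂ > 0.7 are flagged.  Censored rows contribute their censored
log-likelihood (CDF mass), consistent with the fit.

## Synthetic-data generator

Because no observed dataset ships with the package, `simulate` generates
diary tables with the statistical structure the analysis assumes, and the
generating parameters are retained as ground truth for recovery tests.
Study conditions (fixed defaults):

| Quantity | Default | Basis |
|---|---|---|
| Persons × days | 152 × 10 | study design |
| Completion probability | 0.833 | mean 8.33 surveys/person (~1,266 rows) |
| Age | trunc-Normal(69.18, 5.73) on [53, 86], ~66% female | cohort description |
| AARC-gains | BP mean 20.95, BP SD 2.269, WP SD 1.31 (25% WP share) | reported moments + variance decomposition |
| AARC-losses | BP mean 10.13, BP SD 2.834, WP SD 1.549 (23% WP share) | reported moments + variance decomposition |
| Stressors | 5 independent Bernoulli(0.118)/day, severity uniform 1–5 | 0.46–0.72 events/day band |
| Outcome coefficients | published posterior means (β, τ) per design | recovery ground truth |
| Residual SD σ | 0.45 (negative affect), 0.64 (vitality) | see below |
| Skewness α | 4 (negative affect), 0 (vitality) | see below |
| Weekend days | day indices {5, 6} | start weekday not reported; configurable |

σ and α are not reported quantities.  σ defaults make the marginal variance
of the simulated standardized outcome approximately one — the
self-consistency condition implied by modeling a standardized outcome —
and α = 4 gives the residual skew a clearly non-Gaussian but plausible
shape for a floor-heavy affect scale.  AARC scores are simulated at the
scale-score level (the analysis consumes scale scores) as person mean +
daily deviation, clipped to [5, 25]; the clipping rate is reported, and at
the default parameters clipping moves the recovered within-person shares by
well under one percentage point.  Item-level AARC responses consistent
with the scale scores can be generated separately to exercise the scoring
operations.  Missingness is Bernoulli per occasion with at least one
retained occasion per person.

What the generator does **not** emulate: autocorrelated within-person
processes (deviations are iid across days), reactive or planned missingness
(completion is independent of state), discreteness of the affect/vitality
scores (outcomes are continuous between the bounds), day-of-week structure
beyond a weekend flag, and any lagged coupling between stressors and AARC.
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to the
violations real diary data may exhibit.

### Recovery protocol

Recovery fits standardize the outcome with the generator's stored moments
and censoring bounds rather than re-estimating them from the censored
sample: re-standardizing a censored sample shrinks the scale and would bias
every coefficient by a known factor unrelated to the estimator under test.
Fits to real data standardize from the sample, as the analysis
specification describes.

## Numerical choices

- Standardization uses the population-SD convention (ddof = 0).
- Values lying exactly at a censoring bound are coded censored; the
  censored likelihood uses `log_ndtr` (normal family) or the Owen's-T CDF
  clipped away from 0/1 (skew family) for tail stability.
- Leapfrog excursions with |log σ|, |log τ| > 20, |α| > 200 or coordinates
  beyond 10³ return −∞ immediately, so runaway trajectories are rejected
  before overflowing.
- HDI requires ≥ 100 draws; proportions are never rounded in logic.
- The PSIS tail fit follows the standard largest-20%-of-weights rule via
  `arviz.psislw`.
- Sub-seeds for multi-stage runs derive from one user seed via
  `numpy.random.SeedSequence`, so every artifact is reproducible from
  (config, seed).

## Problem sizes used in shipped checks

The packaged tests and the acceptance script run the variance-components
recovery at 2,000 persons × 10 days, and the coefficient-recovery fits at
the study's own 152 × 10 size with 4 chains × (500–700 warmup + 1,000
draws) — enough for bulk ESS well above 1,000 on the slowest-mixing
parameters.  These sizes are the package's reference conditions; larger
runs only sharpen the same comparisons.

## Known limitations

- Single random intercept only: no random slopes, no crossed effects.
- The skew-normal shape is common to all observations (no covariate-
  dependent skewness), matching the target analysis.
- The dense metric stores and factorizes a dim × dim covariance; for
  models with many thousands of parameters the diagonal variant (with more
  draws) would be the practical choice.
- PSIS-LOO treats occasions as exchangeable units; leave-one-person-out is
  not implemented.
- The dual-ROPE decision procedure is reported as specified; it is not a
  calibrated error-rate procedure.
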