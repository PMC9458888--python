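# diaryreact

Bayesian analysis of **daily-diary stress reactivity** moderated by
**awareness of age-related change (AARC)** — a reusable implementation of
the full modeling pipeline for intensive-longitudinal studies of affect and
aging, with a synthetic-data generator in place of the (unavailable) study
data.

Daily-diary designs measure the same people every evening for ~10 days:
daily stressor severity, daily perceptions of age-related gains and losses
(AARC-10 SF), negative affect (SPANE), and subjective vitality.  The
scientific question is whether the within-person (WP) coupling of stressor
severity with same-day affect — the *reactivity slope* — varies with daily
AARC.  The pipeline provides:

- **Scale scoring and long-form CSV I/O** for person-day diary tables.
- **A synthetic-data generator** reproducing the study's conditions
  (152 persons × 10 days, ~83% completion, AARC within-person variance
  shares of 25%/23%, 0.46–0.72 stressor events/day) with known ground
  truth for recovery testing.
- **Two-level censored regression models**: for person *j*, day *i*,

      y*_ij = x_ij' β + u_j + ε_ij,   u_j ~ N(0, τ),

  with y observed as y* censored at the scale bounds; ε is skew-normal
  (mean-parameterized, shape α) for negative affect and normal for
  vitality.  Predictors are standardized long-form and disaggregated into
  between-person means and within-person deviations, with WP two- and
  three-way interaction products.  Priors: β ~ N(0,1), σ, τ ~ half-t(3, 2.5),
  α ~ N(0,4).  Posterior sampling uses a built-in no-U-turn HMC sampler
  with analytic gradients (R-hat/ESS convergence contract enforced).
- **HDI + dual-ROPE inference**: 95% highest-density intervals compared
  against regions of practical equivalence of ±0.05 (main effects) and
  additionally ±0.025 (interactions), with P_meaningful / P_null
  proportions and published-table-shaped summaries.
- **Interaction probing**: reactivity slopes at ±1 SD combinations of WP
  gains/losses, slope differences and the difference-of-differences
  (= 4·β_threeway), quadratic-stress curves.
- **PSIS-LOO model comparison** (elpd, SE, Pareto-k̂ diagnostics).

See `docs/methods.md` for the model, parameter defaults, and design
decisions.

## Worked example

```python
from diaryreact import designs, simulate, build_model_frame, fit, SamplerConfig
from diaryreact.rope import summary_table

truth = designs.negative_affect_truth()        # published estimates as ground truth
table, params = simulate.simulate_dataset(
    designs.default_config(truth), seed=42
)
frame = build_model_frame(table, params.design,
                          outcome_moments=params.outcome_moments)
result = fit(frame,
             sampler_config=SamplerConfig(chains=2, warmup=500, draws=700,
                                          min_ess_bulk=80, rhat_max=1.05),
             seed=7)
rows = ["BP AARC-losses", "WP AARC-losses", "WP stress severity"]
print(summary_table(result, labels=designs.TABLE_LABELS)
      .loc[rows].round(2).iloc[:, :7].to_string())
```

prints (reduced sampler settings for a quick run):

```
                     Est  Error   Low  High  Below_0.05  Within_0.05  Above_0.05
predictor
BP AARC-losses      0.52   0.07  0.38  0.65         0.0          0.0         1.0
WP AARC-losses      0.13   0.03  0.08  0.19         0.0          0.0         1.0
WP stress severity  0.19   0.01  0.16  0.21         0.0          0.0         1.0
```

Each row is a standardized regression coefficient: the posterior mean
(Est), posterior SD (Error), 95% HDI bounds, and the fraction of posterior
draws below/within/above the ±0.05 region of practical equivalence.  Here
all three coefficients fall entirely above the ROPE — people with higher
average AARC-losses report more negative affect, and days with
higher-than-usual losses or stressor severity are days with higher negative
affect — and the recovered values sit within two posterior SDs of the
generating coefficients (0.44, 0.13, 0.20).

The same pipeline is scriptable from the shell:

```bash
diaryreact simulate --design negative_affect --seed 1 --out data/diary.csv
diaryreact fit --data data/diary.csv --design negative_affect \
    --use-truth-moments --seed 1 --out-prefix out/na
diaryreact report --data data/diary.csv --seed 1 --out-prefix out/na \
    --min-ess 200 --rhat-max 1.02 --chains 2 --warmup 500 --draws 700
diaryreact compare --data data/diary.csv --seed 1 --out out/compare.txt
```

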