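"""Posterior sampling: prior predictive, recovery, diagnostics, ICC."""

import numpy as np
import pandas as pd
import pytest

from diaryreact.fit import (
    ConvergenceError,
    fit,
    pointwise_loglik,
    variance_components_icc,
)
from diaryreact.model import FamilySpec, HierarchicalModel, censored_loglik
from diaryreact.preprocess import DesignSpec, ModelFrame
from diaryreact.sampler import SamplerConfig

FAST = SamplerConfig(chains=2, warmup=250, draws=400, min_ess_bulk=50, rhat_max=1.05)


def _sim_frame(seed, n_persons=40, n_per=5, beta=(0.3, 0.6), tau=0.5, sigma=0.4,
               censor_at=None, family="censored_normal"):
    rng = np.random.default_rng(seed)
    J, n = n_persons, n_persons * n_per
    person = np.repeat(np.arange(J), n_per)
    x = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    u = tau * rng.standard_normal(J)
    y = X @ np.array(beta) + u[person] + sigma * rng.standard_normal(n)
    lo, hi = (-np.inf, np.inf) if censor_at is None else censor_at
    code = np.zeros(n, dtype=int)
    code[y <= lo] = -1
    code[y >= hi] = 1
    y = np.clip(y, lo, hi)
    design = DesignSpec(name="sim", outcome="negative_affect", family=family,
                        raw_bounds=(-50, 50))
    return ModelFrame(y=y, censor_code=code, X=X, columns=["intercept", "x"],
                      person_index=person, person_ids=list(range(J)),
                      standardization={}, bounds=(lo, hi), design=design)


class TestFitContract:
    def test_gaussian_recovery_within_two_posterior_sd(self):
        frame = _sim_frame(seed=1)
        res = fit(frame, sampler_config=FAST, seed=2)
        for name, true in [("intercept", 0.3), ("x", 0.6), ("tau", 0.5),
                           ("sigma", 0.4)]:
            m, s = res.posterior_mean(name), res.posterior_sd(name)
            assert abs(m - true) < 2.5 * s, f"{name}: {m} vs {true} (sd {s})"

    def test_seed_reproducible(self):
        frame = _sim_frame(seed=3)
        a = fit(frame, sampler_config=FAST, seed=5)
        b = fit(frame, sampler_config=FAST, seed=5)
        assert np.array_equal(a.posterior, b.posterior)

    def test_convergence_error_names_parameters(self):
        frame = _sim_frame(seed=4)
        strict = SamplerConfig(chains=2, warmup=60, draws=120,
                               min_ess_bulk=1e6)  # unattainable threshold
        with pytest.raises(ConvergenceError, match="ess_bulk"):
            fit(frame, sampler_config=strict, seed=1)

    def test_diagnostics_cover_all_core_parameters(self):
        frame = _sim_frame(seed=6)
        res = fit(frame, sampler_config=FAST, seed=3)
        assert set(res.diagnostics.index) == {"intercept", "x", "sigma", "tau"}
        assert res.diagnostics.notna().all().all()

    def test_prior_predictive_moments(self):
        """With no informative rows, beta draws follow the Normal(0,1) prior."""
        frame = _sim_frame(seed=7, n_persons=2, n_per=1, tau=0.3, sigma=1.0)
        # drop all rows: posterior = prior
        empty = ModelFrame(
            y=frame.y[:0], censor_code=frame.censor_code[:0], X=frame.X[:0],
            columns=frame.columns, person_index=frame.person_index[:0],
            person_ids=frame.person_ids, standardization={},
            bounds=frame.bounds, design=frame.design,
        )
        # the bare prior is heavy-tailed in log sigma/tau, so a warmup
        # covariance estimate is unstable; sample it with the diagonal metric
        cfg = SamplerConfig(chains=2, warmup=300, draws=1500, metric="diag",
                            min_ess_bulk=50, rhat_max=1.1)
        res = fit(empty, sampler_config=cfg, seed=11)
        b = res.draws("x")
        assert b.mean() == pytest.approx(0.0, abs=0.1)
        assert b.std() == pytest.approx(1.0, abs=0.1)

    def test_censored_fit_matches_uncensored_when_bounds_far(self):
        frame = _sim_frame(seed=8, censor_at=(-30.0, 30.0))
        res_c = fit(frame, sampler_config=FAST, seed=4)
        frame_u = _sim_frame(seed=8)
        res_u = fit(frame_u, sampler_config=FAST, seed=4)
        assert np.array_equal(res_c.posterior, res_u.posterior)


class TestCoverage:
    def test_interval_coverage_across_replicates(self):
        """~95% of central 95% posterior intervals should cover the truth."""
        truth = {"intercept": 0.3, "x": 0.6, "tau": 0.5, "sigma": 0.4}
        covered = total = 0
        for seed in range(20):
            frame = _sim_frame(seed=100 + seed, n_persons=30, n_per=5)
            res = fit(frame, sampler_config=SamplerConfig(
                chains=2, warmup=200, draws=300, min_ess_bulk=30, rhat_max=1.2,
            ), seed=seed)
            for name, t in truth.items():
                lo, hi = np.quantile(res.draws(name), [0.025, 0.975])
                covered += int(lo <= t <= hi)
                total += 1
        assert covered / total >= 0.85

    def test_skew_family_recovery(self):
        frame = _sim_frame(seed=9, n_persons=60, n_per=8, sigma=0.5,
                           censor_at=(-1.2, np.inf), family="censored_skew_normal")
        res = fit(frame, sampler_config=SamplerConfig(
            chains=2, warmup=300, draws=500, min_ess_bulk=40, rhat_max=1.1,
        ), seed=12)
        # data generated with alpha=0; its interval should include 0
        lo, hi = np.quantile(res.draws("alpha"), [0.025, 0.975])
        assert lo <= 0.0 <= hi
        assert abs(res.posterior_mean("x") - 0.6) < 2.5 * res.posterior_sd("x")


class TestPointwiseLoglik:
    def test_rows_sum_to_total_and_recompute(self):
        frame = _sim_frame(seed=10, censor_at=(-0.5, 1.5))
        res = fit(frame, sampler_config=FAST, seed=6)
        ll = pointwise_loglik(res)
        n_draws = res.posterior.shape[0] * res.posterior.shape[1]
        assert ll.shape == (n_draws, frame.n_obs)
        assert np.all(np.isfinite(ll))
        model = HierarchicalModel(frame)
        flat = res.posterior.reshape(n_draws, -1)
        rng = np.random.default_rng(0)
        for d in rng.choice(n_draws, 5, replace=False):
            beta, sigma, tau = flat[d, :2], flat[d, 2], flat[d, 3]
            u = flat[d, 4:]
            mu = frame.X @ beta + u[frame.person_index]
            total = censored_loglik(frame.y, frame.censor_code, mu, sigma, 0.0,
                                    frame.bounds)
            assert ll[d].sum() == pytest.approx(total)


class TestVarianceComponents:
    def _balanced(self, seed, tau=1.0, sigma=1.0, J=300, n_per=6):
        rng = np.random.default_rng(seed)
        u = tau * rng.standard_normal(J)
        y = np.repeat(u, n_per) + sigma * rng.standard_normal(J * n_per)
        return pd.DataFrame({
            "person_id": np.repeat(np.arange(J), n_per), "y": y,
        })

    def test_equal_components_give_fifty_percent(self):
        df = self._balanced(seed=1)
        res = variance_components_icc(df, "y", seed=2)
        assert res.wp_share == pytest.approx(50.0, abs=4.0)

    def test_matches_anova_moment_estimator(self):
        df = self._balanced(seed=2, tau=0.8, sigma=0.5)
        res = variance_components_icc(df, "y", seed=3)
        # one-way random-effects ANOVA on balanced data
        y = df["y"].to_numpy()
        g = df.groupby("person_id")["y"]
        n_per = 6
        ms_within = ((y - g.transform("mean")) ** 2).sum() / (len(df) - g.ngroups)
        ms_between = n_per * ((g.mean() - y.mean()) ** 2).sum() / (g.ngroups - 1)
        tau2 = (ms_between - ms_within) / n_per
        anova_share = 100 * ms_within / (ms_within + tau2)
        assert res.wp_share == pytest.approx(anova_share, abs=3.0)

    def test_deterministic(self):
        df = self._balanced(seed=4)
        a = variance_components_icc(df, "y", seed=5)
        b = variance_components_icc(df, "y", seed=5)
        assert a.wp_share == b.wp_share
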