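"""Censored likelihood, log posterior, and gradient correctness."""

import numpy as np
import pytest
from scipy import stats

from diaryreact import skewnorm
from diaryreact.model import (
    FamilySpec,
    HierarchicalModel,
    Priors,
    censored_loglik,
    log_posterior,
)
from diaryreact.preprocess import ModelFrame, DesignSpec


def _toy_frame(rng, n_persons=6, n_per=4, censor_at=None, family="censored_normal"):
    """Small hand-rolled frame: intercept + one slope, optional censoring."""
    J, n = n_persons, n_persons * n_per
    person = np.repeat(np.arange(J), n_per)
    x = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    u = 0.5 * rng.standard_normal(J)
    y = 0.3 + 0.6 * x + u[person] + 0.4 * rng.standard_normal(n)
    lo, hi = (-np.inf, np.inf) if censor_at is None else censor_at
    code = np.zeros(n, dtype=int)
    code[y <= lo] = -1
    code[y >= hi] = 1
    y = np.clip(y, lo, hi)
    design = DesignSpec(
        name="toy", outcome="negative_affect", family=family, raw_bounds=(-50, 50)
    )
    return ModelFrame(
        y=y, censor_code=code, X=X, columns=["intercept", "x"],
        person_index=person, person_ids=list(range(J)),
        standardization={}, bounds=(lo, hi), design=design,
    )


class TestCensoredLoglik:
    def test_uncensored_equals_density_sum(self, rng):
        y = rng.normal(size=20)
        code = np.zeros(20, dtype=int)
        ll = censored_loglik(y, code, 0.1, 1.0, 0.0, (-np.inf, np.inf))
        assert ll == pytest.approx(stats.norm.logpdf(y, 0.1, 1.0).sum())

    def test_all_left_censored_closed_form(self):
        n, L, mu, sigma = 13, -1.0, 0.2, 0.9
        y = np.full(n, L)
        code = np.full(n, -1)
        ll = censored_loglik(y, code, mu, sigma, 0.0, (L, np.inf))
        assert ll == pytest.approx(n * stats.norm.logcdf(L, mu, sigma))

    def test_censoring_mass_matches_monte_carlo(self, rng):
        """Model censoring probability vs simulated censoring frequency."""
        mu, sigma, alpha, L = -0.3, 0.8, 4.0, -1.0
        draws = skewnorm.rvs(mu, sigma, alpha, 2_000_000, rng)
        emp = np.mean(draws <= L)
        model_p = np.exp(skewnorm.logcdf(L, mu, sigma, alpha))
        assert emp == pytest.approx(model_p, abs=1e-3)

    def test_out_of_bounds_uncensored_rejected(self):
        with pytest.raises(ValueError):
            censored_loglik(np.array([-2.0]), np.array([0]), 0.0, 1.0, 0.0, (-1.0, 1.0))


class TestLogPosterior:
    def test_finite_at_random_parameters(self, rng):
        frame = _toy_frame(rng, censor_at=(-1.0, 1.5))
        m = HierarchicalModel(frame)
        for _ in range(20):
            theta = rng.normal(scale=0.5, size=m.n_params)
            assert np.isfinite(log_posterior(theta, m))

    def test_zero_rows_equals_joint_prior(self, rng):
        frame = _toy_frame(rng)
        empty = ModelFrame(
            y=frame.y[:0], censor_code=frame.censor_code[:0], X=frame.X[:0],
            columns=frame.columns, person_index=frame.person_index[:0],
            person_ids=[], standardization={}, bounds=frame.bounds,
            design=frame.design,
        )
        m = HierarchicalModel(empty)
        theta = np.array([0.3, -0.2, np.log(0.7), np.log(0.4)])
        from diaryreact.model import _half_t_logpdf

        expected = (
            stats.norm.logpdf([0.3, -0.2]).sum()
            + _half_t_logpdf(0.7, 2.5, 3.0) + np.log(0.7)
            + _half_t_logpdf(0.4, 2.5, 3.0) + np.log(0.4)
        )
        assert log_posterior(theta, m) == pytest.approx(float(expected))

    @pytest.mark.parametrize("family,censor", [
        ("censored_normal", None),
        ("censored_normal", (-1.0, 1.5)),
        ("censored_skew_normal", (-1.0, np.inf)),
    ])
    @pytest.mark.parametrize("noncentered", [False, True])
    def test_gradient_matches_finite_differences(self, rng, family, censor, noncentered):
        frame = _toy_frame(rng, censor_at=censor, family=family)
        m = HierarchicalModel(frame, noncentered=noncentered)
        theta = 0.3 * rng.standard_normal(m.n_params)
        lp, grad = m.logp_and_grad(theta)
        h = 1e-5
        for i in range(m.n_params):
            tp = theta.copy()
            tp[i] += h
            up = m.logp_and_grad(tp)[0]
            tp[i] -= 2 * h
            dn = m.logp_and_grad(tp)[0]
            assert grad[i] == pytest.approx((up - dn) / (2 * h), rel=1e-4, abs=1e-6)

    def test_skew_family_alpha_zero_matches_normal_family(self, rng):
        frame_n = _toy_frame(rng, censor_at=(-1.0, 2.0), family="censored_normal")
        frame_s = ModelFrame(
            y=frame_n.y, censor_code=frame_n.censor_code, X=frame_n.X,
            columns=frame_n.columns, person_index=frame_n.person_index,
            person_ids=frame_n.person_ids, standardization={},
            bounds=frame_n.bounds,
            design=DesignSpec(name="toy_s", outcome="negative_affect",
                              family="censored_skew_normal", raw_bounds=(-50, 50)),
        )
        mn = HierarchicalModel(frame_n)
        ms = HierarchicalModel(frame_s)
        theta_n = 0.2 * rng.standard_normal(mn.n_params)
        theta_s = np.insert(theta_n, mn.p + 2, 0.0)  # alpha = 0
        lp_n = mn.logp_and_grad(theta_n)[0]
        lp_s = ms.logp_and_grad(theta_s)[0]
        # the joints differ only by the (normalized) shape prior at alpha = 0
        alpha_prior = stats.norm.logpdf(0.0, scale=4.0)
        assert lp_s == pytest.approx(lp_n + alpha_prior, abs=1e-10)

    def test_wide_bounds_match_uncensored_model(self, rng):
        frame = _toy_frame(rng)
        m_inf = HierarchicalModel(frame, FamilySpec("censored_normal"))
        m_wide = HierarchicalModel(
            frame, FamilySpec("censored_normal", lower=-1e8, upper=1e8)
        )
        theta = 0.2 * rng.standard_normal(m_inf.n_params)
        assert m_wide.logp_and_grad(theta)[0] == pytest.approx(
            m_inf.logp_and_grad(theta)[0], abs=1e-10
        )

    def test_pointwise_rows_sum_to_censored_loglik(self, rng):
        frame = _toy_frame(rng, censor_at=(-1.0, 1.5))
        m = HierarchicalModel(frame)
        beta = np.array([0.2, 0.5])
        u = 0.3 * rng.standard_normal(m.J)
        rows = m.pointwise_loglik_row(beta, 0.5, 0.4, 0.0, u)
        mu = frame.X @ beta + u[frame.person_index]
        total = censored_loglik(
            frame.y, frame.censor_code, mu, 0.5, 0.0, frame.bounds
        )
        assert rows.sum() == pytest.approx(total)


def test_priors_validate():
    with pytest.raises(ValueError):
        Priors(coef_sd=-1)
    with pytest.raises(ValueError):
        FamilySpec("censored_normal", lower=2.0, upper=1.0)
    with pytest.raises(ValueError):
        FamilySpec("lognormal")
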