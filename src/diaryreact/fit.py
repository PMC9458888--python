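"""Posterior sampling front-end: fit(), diagnostics, variance components.

``fit`` runs the HMC sampler on a :class:`HierarchicalModel`, transforms the
draws back to the constrained scale (sigma, tau, u_j = tau z_j) and checks
split R-hat and bulk ESS for every reported parameter, raising
:class:`ConvergenceError` naming the offenders when the contract
(R-hat <= 1.01, bulk ESS >= 400 by default) is not met.

``variance_components_icc`` fits the intercept-only two-level normal model.
Because that model is uncensored and Gaussian, the person intercepts are
marginalized analytically (compound-symmetry likelihood), leaving a
3-parameter posterior that is sampled with an affine-invariant ensemble
sampler; the within-person variance share is 100 sigma^2/(sigma^2+tau^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FamilySpec, HierarchicalModel, Priors, _half_t_logpdf
from .preprocess import ModelFrame, person_disaggregate, standardize_long
from .sampler import SamplerConfig, run_chains

__all__ = [
    "ConvergenceError",
    "FitResult",
    "fit",
    "pointwise_loglik",
    "VarianceComponents",
    "variance_components_icc",
]


class ConvergenceError(RuntimeError):
    """Raised when sampler diagnostics violate the convergence contract."""


@dataclass
class FitResult:
    """Posterior draws (constrained scale) plus diagnostics and metadata."""

    posterior: np.ndarray          # (chains, draws, n_params)
    param_names: list[str]
    diagnostics: pd.DataFrame      # rhat / ess_bulk / ess_tail per core parameter
    metadata: dict
    model: HierarchicalModel | None = field(default=None, repr=False)

    def draws(self, name: str) -> np.ndarray:
        """Pooled post-warmup draws of one parameter (chains flattened)."""
        i = self.param_names.index(name)
        return self.posterior[:, :, i].reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.draws(name).mean())

    def posterior_sd(self, name: str) -> float:
        return float(self.draws(name).std(ddof=1))

    @property
    def core_names(self) -> list[str]:
        return [n for n in self.param_names if not n.startswith("u[")]

    def to_csv(self, draws_path, diagnostics_path=None) -> None:
        flat = self.posterior.reshape(-1, self.posterior.shape[-1])
        pd.DataFrame(flat, columns=self.param_names).to_csv(draws_path, index=False)
        if diagnostics_path is not None:
            self.diagnostics.to_csv(diagnostics_path)


def _compute_diagnostics(draws_3d: np.ndarray, names: list[str]) -> pd.DataFrame:
    import arviz as az

    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(names):
            chain_draws = draws_3d[:, :, i]
            rows[name] = {
                "rhat": float(az.rhat(chain_draws.copy())),
                "ess_bulk": float(az.ess(chain_draws.copy(), method="bulk")),
                "ess_tail": float(az.ess(chain_draws.copy(), method="tail")),
            }
    return pd.DataFrame(rows).T


def fit(
    model_frame: ModelFrame,
    family: FamilySpec | None = None,
    priors: Priors = Priors(),
    sampler_config: SamplerConfig = SamplerConfig(),
    seed: int = 0,
    check_convergence: bool = True,
    noncentered: bool = False,
) -> FitResult:
    """Sample the censored hierarchical regression posterior."""
    model = HierarchicalModel(model_frame, family, priors, noncentered=noncentered)
    raw, chain_stats = run_chains(
        model.logp_and_grad, model.initial_position, sampler_config, seed
    )

    # constrain: sigma = exp, tau = exp, u_j = tau * z_j when non-centered
    post = raw.copy()
    p = model.p
    post[:, :, p] = np.exp(raw[:, :, p])
    post[:, :, p + 1] = np.exp(raw[:, :, p + 1])
    k = p + 2 + (1 if model.family.skewed else 0)
    if model.noncentered:
        post[:, :, k:] = post[:, :, p + 1][:, :, None] * raw[:, :, k:]

    names = model.param_names
    core = [n for n in names if not n.startswith("u[")]
    core_idx = [names.index(n) for n in core]
    diagnostics = _compute_diagnostics(post[:, :, core_idx], core)

    result = FitResult(
        posterior=post,
        param_names=names,
        diagnostics=diagnostics,
        metadata={
            "seed": seed,
            "chains": sampler_config.chains,
            "warmup": sampler_config.warmup,
            "draws": sampler_config.draws,
            "family": model.family.family,
            "bounds": (model.family.lower, model.family.upper),
            "chain_stats": chain_stats,
            "design": model_frame.design.name,
        },
        model=model,
    )
    if check_convergence:
        bad = []
        for name, row in diagnostics.iterrows():
            if row["rhat"] > sampler_config.rhat_max:
                bad.append(f"{name}: rhat={row['rhat']:.3f}")
            if row["ess_bulk"] < sampler_config.min_ess_bulk:
                bad.append(f"{name}: ess_bulk={row['ess_bulk']:.0f}")
        if bad:
            raise ConvergenceError(
                "sampler did not meet the convergence contract: " + "; ".join(bad)
            )
    return result


def pointwise_loglik(fit_result: FitResult, frame: ModelFrame | None = None) -> np.ndarray:
    """(draws, observations) matrix of censored log-likelihood contributions."""
    model = fit_result.model
    if model is None:
        if frame is None:
            raise ValueError("fit result carries no model; pass the model frame")
        model = HierarchicalModel(frame, FamilySpec.for_frame(frame))
    flat = fit_result.posterior.reshape(-1, fit_result.posterior.shape[-1])
    p = model.p
    k = p + 2 + (1 if model.family.skewed else 0)
    out = np.empty((flat.shape[0], len(model.y)))
    for d in range(flat.shape[0]):
        theta = flat[d]
        alpha = theta[p + 2] if model.family.skewed else 0.0
        out[d] = model.pointwise_loglik_row(
            theta[:p], theta[p], theta[p + 1], alpha, theta[k:]
        )
    return out


# ---------------------------------------------------------------------------
# variance components / ICC
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Posterior summary of the intercept-only two-level model."""

    wp_share: float        # posterior mean of 100 sigma^2 / (sigma^2 + tau^2), in %
    sigma: float
    tau: float
    draws: pd.DataFrame    # columns mu, sigma, tau, wp_share


def _cs_loglik_factory(y: np.ndarray, person_index: np.ndarray, priors: Priors):
    """Marginal likelihood of the compound-symmetry (random-intercept) model.

    For person j with n_j observations, mean ybar_j and within-person sum of
    squares ss_j, the marginal covariance sigma^2 I + tau^2 J gives

        logdet = (n_j - 1) log sigma^2 + log(sigma^2 + n_j tau^2)
        quad   = ss_j / sigma^2 + n_j (ybar_j - mu)^2 / (sigma^2 + n_j tau^2)
    """
    J = person_index.max() + 1
    n_j = np.bincount(person_index, minlength=J).astype(float)
    ybar = np.bincount(person_index, weights=y, minlength=J) / n_j
    ss = np.bincount(person_index, weights=(y - ybar[person_index]) ** 2, minlength=J)
    n_total = len(y)

    def logpost(theta):
        mu, log_sigma, log_tau = theta
        if abs(log_sigma) > 15 or abs(log_tau) > 15:
            return -np.inf
        s2 = np.exp(2 * log_sigma)
        t2 = np.exp(2 * log_tau)
        denom = s2 + n_j * t2
        logdet = float(np.sum((n_j - 1) * np.log(s2) + np.log(denom)))
        quad = float(np.sum(ss) / s2 + np.sum(n_j * (ybar - mu) ** 2 / denom))
        ll = -0.5 * (n_total * np.log(2 * np.pi) + logdet + quad)
        lp = (
            -0.5 * mu**2
            + _half_t_logpdf(np.sqrt(s2), priors.sd_scale, priors.sd_df) + log_sigma
            + _half_t_logpdf(np.sqrt(t2), priors.sd_scale, priors.sd_df) + log_tau
        )
        return ll + float(lp)

    return logpost


def variance_components_icc(
    table,
    outcome: str,
    seed: int = 0,
    n_steps: int = 1200,
    n_burn: int = 400,
    n_walkers: int = 12,
    priors: Priors = Priors(),
) -> VarianceComponents:
    """Within-person variance share (%) of an outcome via a two-level model.

    ``table`` may be a DiaryTable or any DataFrame with ``person_id`` and the
    outcome column.  The outcome is standardized long-form before fitting
    (the share is scale-invariant).
    """
    import emcee

    df = table.frame if hasattr(table, "frame") else table
    sub = df[["person_id", outcome]].dropna()
    if sub["person_id"].nunique() < 2:
        raise ValueError("need at least two persons")
    codes, _ = pd.factorize(sub["person_id"])
    y, _, _ = standardize_long(sub[outcome].to_numpy(dtype=float))
    logpost = _cs_loglik_factory(y, codes, priors)

    rng = np.random.default_rng(seed)
    # moment-based starting point, scattered across walkers
    bp, wp = person_disaggregate(y, codes)
    s0 = max(wp.std(), 0.05)
    t0 = max(bp.std(), 0.05)
    p0 = np.column_stack([
        rng.normal(0.0, 0.02, n_walkers),
        np.log(s0) + rng.normal(0.0, 0.05, n_walkers),
        np.log(t0) + rng.normal(0.0, 0.05, n_walkers),
    ])
    sampler = emcee.EnsembleSampler(n_walkers, 3, logpost)
    sampler.random_state = np.random.RandomState(seed + 1).get_state()
    sampler.run_mcmc(p0, n_steps)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    mu, sigma, tau = chain[:, 0], np.exp(chain[:, 1]), np.exp(chain[:, 2])
    share = 100.0 * sigma**2 / (sigma**2 + tau**2)
    draws = pd.DataFrame({"mu": mu, "sigma": sigma, "tau": tau, "wp_share": share})
    return VarianceComponents(
        wp_share=float(share.mean()),
        sigma=float(sigma.mean()),
        tau=float(tau.mean()),
        draws=draws,
    )
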