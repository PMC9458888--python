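"""Two-level censored (skew-)normal regression: likelihood, priors, posterior.

The model for person j, day i is

    y*_ij = x_ij' beta + u_j + e_ij,   u_j ~ Normal(0, tau),
    e_ij ~ SkewNormal(mean 0, sd sigma, shape alpha)   (alpha = 0: normal),
    y_ij  = censor(y*_ij, [L, U]),

with weakly informative priors: Normal(0, 1) on the intercept and each
coefficient, half-t(df 3, scale 2.5) on sigma and on tau, Normal(0, 4) on
the skewness shape.  Sampling operates on an unconstrained vector
(beta, log sigma, log tau, alpha, z); log-Jacobian terms for the log
transforms are included.  The person intercepts are parameterized either
centered (z_j = u_j; the default — daily diaries give each person several
informative occasions) or non-centered (u_j = tau z_j, better when the
per-person information is weak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import skewnorm
from .preprocess import ModelFrame

__all__ = [
    "Priors",
    "FamilySpec",
    "HierarchicalModel",
    "censored_loglik",
    "log_posterior",
]


@dataclass(frozen=True)
class Priors:
    coef_sd: float = 1.0       # Normal(0, coef_sd) on intercept + slopes
    sd_scale: float = 2.5      # half-t scale for sigma and tau
    sd_df: float = 3.0         # half-t df
    skew_sd: float = 4.0       # Normal(0, skew_sd) on alpha

    def __post_init__(self):
        if min(self.coef_sd, self.sd_scale, self.sd_df, self.skew_sd) <= 0:
            raise ValueError("prior scales and df must be > 0")


@dataclass(frozen=True)
class FamilySpec:
    """Outcome family and standardized censoring bounds (may be infinite)."""

    family: str  # "censored_normal" | "censored_skew_normal"
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.family not in ("censored_normal", "censored_skew_normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    @property
    def skewed(self) -> bool:
        return self.family == "censored_skew_normal"

    @classmethod
    def for_frame(cls, frame: ModelFrame) -> "FamilySpec":
        return cls(frame.design.family, *frame.bounds)


def _half_t_logpdf(x, scale, df):
    # density of |T|, T ~ t_df(0, scale); constant kept so priors integrate to 1
    c = (
        np.log(2.0)
        + gammaln((df + 1) / 2)
        - gammaln(df / 2)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
    )
    return c - (df + 1) / 2 * np.log1p(x**2 / (df * scale**2))


def _half_t_dlogpdf(x, scale, df):
    return -(df + 1) * x / (df * scale**2 + x**2)


def censored_loglik(y, censor_code, mu, sigma, alpha, bounds) -> float:
    """Total censored log-likelihood.

    Uncensored rows contribute the density at y, left-censored rows the CDF
    mass at the lower bound, right-censored rows the upper-tail mass.
    """
    y = np.asarray(y, dtype=float)
    code = np.asarray(censor_code)
    lo, hi = bounds
    obs = code == 0
    if np.any((y[obs] < lo) | (y[obs] > hi)):
        raise ValueError("uncensored outcome values outside the censoring bounds")
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    total = float(np.sum(skewnorm.logpdf(y[obs], mu[obs], sigma, alpha)))
    left = code == -1
    if left.any():
        total += float(np.sum(skewnorm.logcdf(lo, mu[left], sigma, alpha)))
    right = code == 1
    if right.any():
        total += float(np.sum(skewnorm.logsf(hi, mu[right], sigma, alpha)))
    return total


class HierarchicalModel:
    """Posterior density and gradient on the unconstrained parameter space."""

    def __init__(self, frame: ModelFrame, family: FamilySpec | None = None,
                 priors: Priors = Priors(), noncentered: bool = False):
        self.frame = frame
        self.family = family if family is not None else FamilySpec.for_frame(frame)
        self.priors = priors
        self.noncentered = noncentered
        self.X = frame.X
        self.y = frame.y
        self.code = frame.censor_code
        self.person = frame.person_index
        self.p = self.X.shape[1]
        self.J = frame.n_persons
        self._obs = self.code == 0
        self._left = self.code == -1
        self._right = self.code == 1
        if self._left.any() and not np.isfinite(self.family.lower):
            raise ValueError("left-censored rows but lower bound is -inf")
        if self._right.any() and not np.isfinite(self.family.upper):
            raise ValueError("right-censored rows but upper bound is +inf")

    # -- parameter vector layout: [beta (p), log_sigma, log_tau, (alpha), z (J)]
    @property
    def n_params(self) -> int:
        return self.p + 2 + (1 if self.family.skewed else 0) + self.J

    @property
    def param_names(self) -> list[str]:
        names = list(self.frame.columns) + ["sigma", "tau"]
        if self.family.skewed:
            names.append("alpha")
        names += [f"u[{j}]" for j in range(self.J)]
        return names

    def unpack(self, theta: np.ndarray):
        p = self.p
        beta = theta[:p]
        log_sigma = theta[p]
        log_tau = theta[p + 1]
        k = p + 2
        alpha = theta[k] if self.family.skewed else 0.0
        if self.family.skewed:
            k += 1
        z = theta[k:]
        return beta, log_sigma, log_tau, alpha, z

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(self.n_params)
        p = self.p
        theta[p] = np.log(0.5) + 0.05 * rng.standard_normal()     # sigma
        theta[p + 1] = np.log(0.5) + 0.05 * rng.standard_normal() # tau
        return theta

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        beta, log_sigma, log_tau, alpha, z = self.unpack(theta)
        # reject runaway leapfrog excursions before they overflow
        if (abs(log_sigma) > 20 or abs(log_tau) > 20 or abs(alpha) > 200
                or np.max(np.abs(beta)) > 1e3
                or (z.size and np.max(np.abs(z)) > 1e3)):
            return -np.inf, np.zeros_like(theta)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_and_grad(theta)

    def _logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        beta, log_sigma, log_tau, alpha, z = self.unpack(theta)
        sigma = np.exp(log_sigma)
        tau = np.exp(log_tau)
        u = tau * z if self.noncentered else z
        mu = self.X @ beta + u[self.person]

        lo, hi = self.family.lower, self.family.upper
        lp = 0.0
        dmu = np.zeros(len(self.y))
        dsig_rows = 0.0
        dalpha_rows = 0.0

        obs = self._obs
        lp += float(np.sum(skewnorm.logpdf(self.y[obs], mu[obs], sigma, alpha)))
        gm, gs, ga = skewnorm.logpdf_grad(self.y[obs], mu[obs], sigma, alpha)
        dmu[obs] = gm
        dsig_rows += float(np.sum(gs))
        dalpha_rows += float(np.sum(ga))

        if self._left.any():
            lp += float(np.sum(skewnorm.logcdf(lo, mu[self._left], sigma, alpha)))
            # partials are w.r.t. (mu, sigma, alpha) at the fixed bound
            gm, gs, ga = skewnorm.logcdf_grad(lo, mu[self._left], sigma, alpha)
            dmu[self._left] = gm
            dsig_rows += float(np.sum(gs))
            dalpha_rows += float(np.sum(ga))
        if self._right.any():
            lp += float(np.sum(skewnorm.logsf(hi, mu[self._right], sigma, alpha)))
            gm, gs, ga = skewnorm.logsf_grad(hi, mu[self._right], sigma, alpha)
            dmu[self._right] = gm
            dsig_rows += float(np.sum(gs))
            dalpha_rows += float(np.sum(ga))

        # priors (+ log-Jacobians of the log transforms), fully normalized
        log2pi = np.log(2.0 * np.pi)
        lp += float(
            -0.5 * np.sum(beta**2) / pr.coef_sd**2
            - self.p * (np.log(pr.coef_sd) + 0.5 * log2pi)
        )
        lp += float(_half_t_logpdf(sigma, pr.sd_scale, pr.sd_df)) + log_sigma
        lp += float(_half_t_logpdf(tau, pr.sd_scale, pr.sd_df)) + log_tau
        if self.noncentered:
            lp += float(-0.5 * np.sum(z**2) - 0.5 * self.J * log2pi)
        else:
            lp += float(
                -self.J * (log_tau + 0.5 * log2pi) - 0.5 * np.sum(z**2) / tau**2
            )
        if self.family.skewed:
            lp += float(
                -0.5 * alpha**2 / pr.skew_sd**2 - np.log(pr.skew_sd) - 0.5 * log2pi
            )

        grad = np.zeros_like(theta)
        grad[: self.p] = self.X.T @ dmu - beta / pr.coef_sd**2
        grad[self.p] = (dsig_rows + _half_t_dlogpdf(sigma, pr.sd_scale, pr.sd_df)) * sigma + 1.0
        du = np.bincount(self.person, weights=dmu, minlength=self.J)
        half_t_tau = _half_t_dlogpdf(tau, pr.sd_scale, pr.sd_df) * tau
        if self.noncentered:
            # d mu / d tau = z_j
            grad[self.p + 1] = float(np.sum(du * z)) * tau + half_t_tau + 1.0
        else:
            grad[self.p + 1] = (
                -self.J + float(np.sum(z**2)) / tau**2 + half_t_tau + 1.0
            )
        k = self.p + 2
        if self.family.skewed:
            grad[k] = dalpha_rows - alpha / pr.skew_sd**2
            k += 1
        grad[k:] = (tau * du - z) if self.noncentered else (du - z / tau**2)
        return lp, grad

    # -- per-row likelihood, for PSIS-LOO ------------------------------
    def pointwise_loglik_row(self, beta, sigma, tau, alpha, u) -> np.ndarray:
        """Censored log-likelihood contribution of every row, one draw."""
        mu = self.X @ beta + u[self.person]
        out = np.empty(len(self.y))
        out[self._obs] = skewnorm.logpdf(self.y[self._obs], mu[self._obs], sigma, alpha)
        if self._left.any():
            out[self._left] = skewnorm.logcdf(self.family.lower, mu[self._left], sigma, alpha)
        if self._right.any():
            out[self._right] = skewnorm.logsf(self.family.upper, mu[self._right], sigma, alpha)
        return out


def log_posterior(theta, model: HierarchicalModel) -> float:
    """Unnormalized log posterior at an unconstrained parameter vector."""
    return model.logp_and_grad(np.asarray(theta, dtype=float))[0]
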