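"""Mean-parameterized skew-normal distribution.

The regression models act on the *mean* of the outcome, so the skew normal
is parameterized by its mean ``mu``, standard deviation ``sigma`` and shape
``alpha`` (identity links).  Internally these map to the usual
location-scale form (xi, omega, alpha):

    delta = alpha / sqrt(1 + alpha^2)
    omega = sigma / sqrt(1 - 2 delta^2 / pi)
    xi    = mu - omega * delta * sqrt(2 / pi)

With ``alpha = 0`` the distribution reduces exactly to Normal(mu, sigma).
The CDF is Phi(z) - 2 T(z, alpha) with Owen's T; both T partials have
closed forms, which the sampler's analytic gradients rely on:

    dT/dh = -phi(h) (Phi(alpha h) - 1/2)
    dT/da = exp(-h^2 (1 + a^2) / 2) / (2 pi (1 + a^2))
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr, owens_t

__all__ = [
    "to_location_scale",
    "logpdf",
    "pdf",
    "cdf",
    "logcdf",
    "logsf",
    "rvs",
]

_B = np.sqrt(2.0 / np.pi)


def to_location_scale(mu, sigma, alpha):
    """Map mean parameters (mu, sigma, alpha) to (xi, omega, alpha)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    alpha = np.asarray(alpha, dtype=float)
    delta = alpha / np.sqrt(1.0 + alpha**2)
    c = np.sqrt(1.0 - (_B * delta) ** 2)
    omega = sigma / c
    xi = np.asarray(mu, dtype=float) - omega * delta * _B
    return xi, omega


def logpdf(y, mu, sigma, alpha):
    """Log density of the mean-parameterized skew normal."""
    xi, omega = to_location_scale(mu, sigma, alpha)
    z = (np.asarray(y, dtype=float) - xi) / omega
    return (
        np.log(2.0)
        - np.log(omega)
        - 0.5 * np.log(2.0 * np.pi)
        - 0.5 * z**2
        + log_ndtr(np.asarray(alpha, dtype=float) * z)
    )


def pdf(y, mu, sigma, alpha):
    return np.exp(logpdf(y, mu, sigma, alpha))


def cdf(y, mu, sigma, alpha):
    """CDF via Owen's T: F(y) = Phi(z) - 2 T(z, alpha)."""
    xi, omega = to_location_scale(mu, sigma, alpha)
    z = (np.asarray(y, dtype=float) - xi) / omega
    return np.clip(ndtr(z) - 2.0 * owens_t(z, alpha), 0.0, 1.0)


def logcdf(y, mu, sigma, alpha):
    xi, omega = to_location_scale(mu, sigma, alpha)
    z = (np.asarray(y, dtype=float) - xi) / omega
    if np.all(np.asarray(alpha) == 0):
        return log_ndtr(z)
    f = np.clip(ndtr(z) - 2.0 * owens_t(z, alpha), 0.0, 1.0)
    return np.log(np.maximum(f, 1e-300))


def logsf(y, mu, sigma, alpha):
    xi, omega = to_location_scale(mu, sigma, alpha)
    z = (np.asarray(y, dtype=float) - xi) / omega
    if np.all(np.asarray(alpha) == 0):
        return log_ndtr(-z)
    f = np.clip(ndtr(z) - 2.0 * owens_t(z, alpha), 0.0, 1.0)
    return np.log(np.maximum(1.0 - f, 1e-300))


def rvs(mu, sigma, alpha, size, rng: np.random.Generator):
    """Draw skew-normal variates with mean mu, SD sigma, shape alpha.

    Uses the additive representation: Z = delta |U| + sqrt(1-delta^2) V
    with U, V iid standard normal.
    """
    alpha = float(alpha)
    delta = alpha / np.sqrt(1.0 + alpha**2)
    u = np.abs(rng.standard_normal(size))
    v = rng.standard_normal(size)
    z = delta * u + np.sqrt(1.0 - delta**2) * v
    xi, omega = to_location_scale(mu, sigma, alpha)
    return xi + omega * z


# ---------------------------------------------------------------------------
# Gradient building blocks (used by the HMC model, exercised in tests via
# finite differences).  All return per-element partials w.r.t. the *mean*
# parameterization.
# ---------------------------------------------------------------------------

def _param_partials(sigma, alpha):
    """Partials of (xi, omega) w.r.t. (mu, sigma, alpha) at fixed mean params."""
    alpha = np.asarray(alpha, dtype=float)
    delta = alpha / np.sqrt(1.0 + alpha**2)
    ddelta = (1.0 + alpha**2) ** -1.5
    c2 = 1.0 - (_B * delta) ** 2
    c = np.sqrt(c2)
    omega = sigma / c
    # omega = sigma * c^-1 ;  dc/ddelta = -B^2 delta / c
    domega_dsigma = 1.0 / c
    domega_ddelta = sigma * _B**2 * delta / (c2 * c)
    domega_dalpha = domega_ddelta * ddelta
    # xi = mu - omega delta B
    dxi_dmu = 1.0
    dxi_dsigma = -domega_dsigma * delta * _B
    dxi_dalpha = -_B * (delta * domega_dalpha + omega * ddelta)
    return delta, omega, dxi_dmu, dxi_dsigma, dxi_dalpha, domega_dsigma, domega_dalpha


def logpdf_grad(y, mu, sigma, alpha):
    """(d/dmu, d/dsigma, d/dalpha) of logpdf, elementwise in y and mu."""
    (_, omega, dxi_dmu, dxi_dsigma, dxi_dalpha,
     domega_dsigma, domega_dalpha) = _param_partials(sigma, alpha)
    xi = np.asarray(mu, dtype=float) - omega * (alpha / np.sqrt(1 + alpha**2)) * _B
    z = (np.asarray(y, dtype=float) - xi) / omega
    az = alpha * z
    # phi(az)/Phi(az), computed in logs for stability in the deep tail
    ratio = np.exp(-0.5 * az**2 - 0.5 * np.log(2.0 * np.pi) - log_ndtr(az))
    dlp_dz = -z + alpha * ratio
    dlp_dxi = -dlp_dz / omega
    dlp_domega = -1.0 / omega - z * dlp_dz / omega
    dlp_dalpha_expl = z * ratio
    d_mu = dlp_dxi * dxi_dmu
    d_sigma = dlp_domega * domega_dsigma + dlp_dxi * dxi_dsigma
    d_alpha = dlp_dalpha_expl + dlp_domega * domega_dalpha + dlp_dxi * dxi_dalpha
    return d_mu, d_sigma, d_alpha


def _cdf_partials(y, mu, sigma, alpha):
    """F, dF/dz, dF/dalpha(explicit), z, omega and parameter partials at y."""
    (_, omega, dxi_dmu, dxi_dsigma, dxi_dalpha,
     domega_dsigma, domega_dalpha) = _param_partials(sigma, alpha)
    xi = np.asarray(mu, dtype=float) - omega * (alpha / np.sqrt(1 + alpha**2)) * _B
    z = (np.asarray(y, dtype=float) - xi) / omega
    dF_dz = 2.0 * np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi) * ndtr(alpha * z)  # SN pdf at z
    dF_dalpha = -np.exp(-0.5 * z**2 * (1.0 + alpha**2)) / (np.pi * (1.0 + alpha**2))
    dz_dmu = -dxi_dmu / omega
    dz_dsigma = -(dxi_dsigma + z * domega_dsigma) / omega
    dz_dalpha = -(dxi_dalpha + z * domega_dalpha) / omega
    return z, dF_dz, dF_dalpha, dz_dmu, dz_dsigma, dz_dalpha


def logcdf_grad(y, mu, sigma, alpha):
    """Partials of log F(y) w.r.t. (mu, sigma, alpha)."""
    z, dF_dz, dF_dalpha, dz_dmu, dz_dsigma, dz_dalpha = _cdf_partials(y, mu, sigma, alpha)
    logF = logcdf(y, mu, sigma, alpha)
    inv_F = np.exp(-logF)
    d_mu = inv_F * dF_dz * dz_dmu
    d_sigma = inv_F * dF_dz * dz_dsigma
    d_alpha = inv_F * (dF_dz * dz_dalpha + dF_dalpha)
    return d_mu, d_sigma, d_alpha


def logsf_grad(y, mu, sigma, alpha):
    """Partials of log(1 - F(y)) w.r.t. (mu, sigma, alpha)."""
    z, dF_dz, dF_dalpha, dz_dmu, dz_dsigma, dz_dalpha = _cdf_partials(y, mu, sigma, alpha)
    logS = logsf(y, mu, sigma, alpha)
    inv_S = np.exp(-logS)
    d_mu = -inv_S * dF_dz * dz_dmu
    d_sigma = -inv_S * dF_dz * dz_dsigma
    d_alpha = -inv_S * (dF_dz * dz_dalpha + dF_dalpha)
    return d_mu, d_sigma, d_alpha
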