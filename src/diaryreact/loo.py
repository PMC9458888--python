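"""Expected log predictive density via Pareto-smoothed importance sampling.

``elpd_loo`` estimates leave-one-out predictive accuracy from a
(draws x observations) matrix of pointwise log-likelihoods: per-observation
importance ratios 1/p(y_i | theta^s) are tail-smoothed by a generalized
Pareto fit (PSIS), and the pointwise elpd is the log of the
smoothed-weighted mean likelihood.  Observations with Pareto k-hat above
0.7 are flagged as unreliable.  Model comparison subtracts pointwise
vectors; the SE of a total or difference is sqrt(n * var(pointwise)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["ElpdResult", "elpd_loo", "elpd_difference"]

KHAT_WARN = 0.7


@dataclass(frozen=True)
class ElpdResult:
    """PSIS-LOO estimate: total elpd, its SE, and per-observation detail."""

    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.elpd, self.pointwise.sum()):
            raise ValueError("total elpd must equal the pointwise sum")

    @property
    def n_obs(self) -> int:
        return len(self.pointwise)

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > KHAT_WARN))


def elpd_loo(pointwise_loglik: np.ndarray) -> ElpdResult:
    """PSIS-LOO elpd from a (draws, observations) log-likelihood matrix."""
    import arviz as az

    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be (draws, observations)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise_loglik contains non-finite entries")
    n_draws, n_obs = ll.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # importance ratios are 1/likelihood; psislw smooths the largest tail
        log_smoothed, khat = az.psislw(-ll.T.copy())
    log_smoothed = np.asarray(log_smoothed)        # normalized log weights
    khat = np.asarray(khat, dtype=float)
    pointwise = logsumexp(log_smoothed + ll.T, axis=1)
    if np.any(khat > KHAT_WARN):
        warnings.warn(
            f"{int(np.sum(khat > KHAT_WARN))} observations have Pareto k-hat > "
            f"{KHAT_WARN}; their LOO contributions are unreliable",
            stacklevel=2,
        )
    se = float(np.sqrt(n_obs * np.var(pointwise, ddof=0)))
    return ElpdResult(
        elpd=float(pointwise.sum()), se=se, pointwise=pointwise, pareto_k=khat
    )


def elpd_difference(reference: ElpdResult, challenger: ElpdResult):
    """Challenger-minus-reference elpd difference and its SE.

    Positive values favor the challenger.  Both results must be computed on
    the same observations in the same order.
    """
    if reference.n_obs != challenger.n_obs:
        raise ValueError("elpd results cover different numbers of observations")
    d = challenger.pointwise - reference.pointwise
    diff = float(d.sum())
    se = float(np.sqrt(len(d) * np.var(d, ddof=0)))
    return diff, se
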