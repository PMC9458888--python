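"""Dynamic-trajectory Hamiltonian Monte Carlo (no-U-turn sampler).

Gradient-based posterior sampling with the standard modern recipe:
multinomial sampling over a trajectory that is doubled until the path
starts to double back on itself (the no-U-turn criterion), dual-averaging
step-size adaptation toward a target acceptance statistic, and a mass
matrix estimated from warmup draws in two refinement rounds.  The metric
is dense by default — hierarchical regressions couple the person-level
coefficients to the random intercepts, and a diagonal metric leaves that
collective direction slow — with correlations shrunk toward zero while the
warmup sample is small; a diagonal variant is available.  All randomness
flows through one numpy Generator per chain, so runs are reproducible from
a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy.linalg import solve_triangular

__all__ = ["SamplerConfig", "run_chain", "run_chains"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE = 1000.0  # energy error treated as a divergent transition


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    max_treedepth: int = 8
    init_step: float = 0.1
    metric: str = "dense"  # "dense" | "diag"
    # convergence thresholds enforced by fit()
    rhat_max: float = 1.01
    min_ess_bulk: float = 400.0

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if min(self.warmup, self.draws, self.max_treedepth) < 1:
            raise ValueError("warmup, draws and max_treedepth must be >= 1")
        if self.metric not in ("dense", "diag"):
            raise ValueError("metric must be 'dense' or 'diag'")


# ---------------------------------------------------------------------------
# metrics: kinetic energy  K(p) = p' Sigma p / 2  with  p ~ N(0, Sigma^{-1}),
# where Sigma estimates the posterior covariance
# ---------------------------------------------------------------------------

class _DiagMetric:
    def __init__(self, var: np.ndarray):
        self.var = var
        self._sd_inv = 1.0 / np.sqrt(var)

    def draw_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(len(self.var)) * self._sd_inv

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.var * p

    def kinetic(self, p: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            return 0.5 * float(np.sum(p**2 * self.var))


class _DenseMetric:
    def __init__(self, cov: np.ndarray):
        self.cov = cov
        # Sigma = L L'; momenta are N(0, Sigma^{-1}) so p = L^{-T} z
        self.chol = np.linalg.cholesky(cov)

    def draw_momentum(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.cov.shape[0])
        return solve_triangular(self.chol.T, z, lower=False)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.cov @ p

    def kinetic(self, p: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            return 0.5 * float(p @ (self.cov @ p))


class _Welford:
    """Streaming mean/covariance accumulator for metric estimation."""

    def __init__(self, dim: int, dense: bool):
        self.n = 0
        self.dense = dense
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim)) if dense else np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        if self.dense:
            self.m2 += np.outer(d, x - self.mean)
        else:
            self.m2 += d * (x - self.mean)

    def metric(self):
        dim = len(self.mean)
        if self.n < 2:
            return _DiagMetric(np.ones(dim))
        w = self.n / (self.n + 5.0)
        if not self.dense:
            var = self.m2 / (self.n - 1)
            return _DiagMetric(w * var + (1 - w) * 1e-3)
        cov = self.m2 / (self.n - 1)
        var = np.clip(np.diag(cov).copy(), 1e-10, None)
        # keep scales, shrink correlations while the sample is small relative
        # to the dimension (the sample covariance is singular for n < dim)
        w = self.n / (self.n + 0.5 * dim + 5.0)
        reg = w * cov + (1 - w) * np.diag(var)
        reg[np.diag_indices(dim)] = var + 1e-8
        for ridge in (0.0, 1e-6, 1e-4, 1e-2):
            try:
                return _DenseMetric(reg + ridge * np.diag(var))
            except np.linalg.LinAlgError:
                continue
        return _DiagMetric(var)


class _DualAveraging:
    """Nesterov dual averaging of the log step size."""

    def __init__(self, step0: float, target: float):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.log_step = np.log(step0)
        self.log_step_bar = np.log(step0)
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_stat: float) -> float:
        self.t += 1
        gamma, t0, kappa = 0.05, 10.0, 0.75
        eta = 1.0 / (self.t + t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_step = self.mu - np.sqrt(self.t) / gamma * self.h_bar
        w = self.t ** -kappa
        self.log_step_bar = w * self.log_step + (1 - w) * self.log_step_bar
        return float(np.exp(self.log_step))

    def finalize(self) -> float:
        return float(np.exp(self.log_step_bar))


class _State(NamedTuple):
    x: np.ndarray
    p: np.ndarray
    grad: np.ndarray
    lp: float


class _Tree:
    """A trajectory subtree: edges, multinomial proposal, and statistics."""

    __slots__ = ("minus", "plus", "proposal", "logw", "sum_accept", "n_leaves",
                 "diverged", "turned")

    def __init__(self, minus, plus, proposal, logw, sum_accept, n_leaves,
                 diverged, turned):
        self.minus = minus
        self.plus = plus
        self.proposal = proposal
        self.logw = logw
        self.sum_accept = sum_accept
        self.n_leaves = n_leaves
        self.diverged = diverged
        self.turned = turned


def _leapfrog(logp_grad: LogpGrad, state: _State, step: float, metric) -> _State:
    with np.errstate(over="ignore", invalid="ignore"):
        p = state.p + 0.5 * step * state.grad
        x = state.x + step * metric.velocity(p)
        if not np.all(np.isfinite(x)):
            return _State(x, p, state.grad, -np.inf)
        lp, grad = logp_grad(x)
        p = p + 0.5 * step * grad
    return _State(x, p, grad, lp)


def _energy(state: _State, metric) -> float:
    # overflow to +inf is fine: the leaf is treated as divergent and rejected
    return -state.lp + metric.kinetic(state.p)


def _uturn(minus: _State, plus: _State, metric) -> bool:
    dx = plus.x - minus.x
    return (
        float(dx @ metric.velocity(minus.p)) < 0.0
        or float(dx @ metric.velocity(plus.p)) < 0.0
    )


def _build_tree(logp_grad, state, direction, depth, step, metric, h0, rng):
    if depth == 0:
        nxt = _leapfrog(logp_grad, state, direction * step, metric)
        if not np.isfinite(nxt.lp):
            return _Tree(nxt, nxt, nxt, -np.inf, 0.0, 1, True, False)
        h = _energy(nxt, metric)
        diverged = h - h0 > _DIVERGENCE
        accept = float(np.exp(min(0.0, h0 - h)))
        return _Tree(nxt, nxt, nxt, h0 - h, accept, 1, diverged, False)

    first = _build_tree(logp_grad, state, direction, depth - 1, step, metric, h0, rng)
    if first.diverged or first.turned:
        return first
    edge = first.plus if direction > 0 else first.minus
    second = _build_tree(logp_grad, edge, direction, depth - 1, step, metric, h0, rng)

    minus = first.minus if direction > 0 else second.minus
    plus = second.plus if direction > 0 else first.plus
    logw = np.logaddexp(first.logw, second.logw)
    # multinomial selection between subtree proposals
    if np.log(rng.uniform()) < second.logw - logw:
        proposal = second.proposal
    else:
        proposal = first.proposal
    turned = (
        second.turned
        or first.turned
        or _uturn(minus, plus, metric)
    )
    return _Tree(
        minus, plus, proposal, logw,
        first.sum_accept + second.sum_accept,
        first.n_leaves + second.n_leaves,
        second.diverged, turned,
    )


def _nuts_step(logp_grad, x, lp, grad, step, metric, max_depth, rng):
    """One no-U-turn transition; returns (x, lp, grad, accept_stat, diverged, depth)."""
    p0 = metric.draw_momentum(rng)
    init = _State(x, p0, grad, lp)
    h0 = _energy(init, metric)
    minus = plus = init
    proposal = init
    logw = 0.0
    sum_accept = 0.0
    n_leaves = 0
    diverged = False
    depth = 0
    for depth in range(1, max_depth + 1):
        direction = 1 if rng.uniform() < 0.5 else -1
        edge = plus if direction > 0 else minus
        tree = _build_tree(
            logp_grad, edge, direction, depth - 1, step, metric, h0, rng
        )
        sum_accept += tree.sum_accept
        n_leaves += tree.n_leaves
        if tree.diverged:
            diverged = True
            break
        if tree.turned:
            break
        # biased progressive sampling favors the new subtree
        if np.log(rng.uniform()) < tree.logw - logw:
            proposal = tree.proposal
        if direction > 0:
            plus = tree.plus
        else:
            minus = tree.minus
        logw = np.logaddexp(logw, tree.logw)
        if _uturn(minus, plus, metric):
            break
    accept_stat = sum_accept / max(n_leaves, 1)
    return proposal.x, proposal.lp, proposal.grad, accept_stat, diverged, depth


def run_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Run one chain; returns (draws array, stats dict)."""
    dim = len(x0)
    x = np.asarray(x0, dtype=float).copy()
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log posterior at the initial position")

    dense = config.metric == "dense"
    metric = _DiagMetric(np.ones(dim))
    step = config.init_step
    da = _DualAveraging(step, config.target_accept)
    welford = _Welford(dim, dense)

    draws = np.empty((config.draws, dim))
    accepts = []
    depths = []
    divergences = 0

    w = config.warmup
    refresh = {int(0.45 * w), int(0.8 * w)} if w >= 40 else set()

    for it in range(w + config.draws):
        warming = it < w
        if it == w:
            step = da.finalize()
        x, lp, grad, accept_stat, diverged, depth = _nuts_step(
            logp_grad, x, lp, grad, step, metric, config.max_treedepth, rng
        )
        if warming:
            step = da.update(accept_stat)
            if it >= 0.15 * w:
                welford.update(x)
            if it in refresh and welford.n >= 10:
                metric = welford.metric()
                welford = _Welford(dim, dense)
                da = _DualAveraging(step, config.target_accept)
        else:
            if diverged:
                divergences += 1
            accepts.append(accept_stat)
            depths.append(depth)
            draws[it - w] = x

    stats = {
        "step_size": step,
        "mean_accept": float(np.mean(accepts)) if accepts else np.nan,
        "mean_treedepth": float(np.mean(depths)) if depths else np.nan,
        "divergences": divergences,
    }
    return draws, stats


def run_chains(
    logp_grad: LogpGrad,
    init: Callable[[np.random.Generator], np.ndarray],
    config: SamplerConfig,
    seed: int,
) -> tuple[np.ndarray, list[dict]]:
    """Run ``config.chains`` independent chains -> ((chains, draws, dim), stats)."""
    ss = np.random.SeedSequence(seed)
    out = []
    stats = []
    for child in ss.spawn(config.chains):
        rng = np.random.default_rng(child)
        x0 = init(rng)
        d, s = run_chain(logp_grad, x0, config, rng)
        out.append(d)
        stats.append(s)
    return np.stack(out), stats
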