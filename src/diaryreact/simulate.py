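"""Synthetic daily-diary generator.

Emulates the structure of a 10-day evening-diary study of middle-aged and
older adults: ~152 persons, ~83% survey completion, awareness-of-aging
scores with mostly between-person variance (within-person shares near
25%/23% for gains/losses), sparse stressor endorsements (about 0.5-0.7
events per day), and bounded affect/vitality outcomes generated from the
two-level censored (skew-)normal regression with a known coefficient
vector, so that model fits can be checked against ground truth.

AARC is simulated at scale-score level (the analysis consumes scale
scores); item-level responses consistent with the scores can be generated
separately to exercise the scoring operations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import skewnorm
from .data import ALL_COLUMNS, DiaryTable
from .preprocess import DesignSpec, ModelFrame, build_model_frame
from .scales import N_STRESSORS

__all__ = [
    "AarcComponents",
    "StressorModel",
    "CovariateModel",
    "TrueParameters",
    "GeneratorConfig",
    "simulate_persons",
    "simulate_aarc",
    "simulate_aarc_items",
    "simulate_stressors",
    "simulate_outcome",
    "apply_missingness",
    "simulate_dataset",
]


@dataclass(frozen=True)
class AarcComponents:
    """Between/within-person variance components for one AARC subscale."""

    bp_mean: float
    bp_sd: float
    wp_sd: float

    def __post_init__(self):
        if self.bp_sd <= 0 or self.wp_sd < 0:
            raise ValueError("bp_sd must be > 0 and wp_sd >= 0")

    @property
    def wp_share(self) -> float:
        """Within-person variance share (%) implied by the components."""
        return 100.0 * self.wp_sd**2 / (self.bp_sd**2 + self.wp_sd**2)


@dataclass(frozen=True)
class StressorModel:
    """Independent Bernoulli exposure per stressor; iid severity where endorsed."""

    exposure_prob: float = 0.118   # 5 stressors -> ~0.59 events/day
    severity_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

    def __post_init__(self):
        if not 0 <= self.exposure_prob <= 1:
            raise ValueError("exposure_prob must be in [0, 1]")
        if len(self.severity_probs) != 5 or abs(sum(self.severity_probs) - 1) > 1e-9:
            raise ValueError("severity_probs must be 5 probabilities summing to 1")


@dataclass(frozen=True)
class CovariateModel:
    """Baseline covariate distributions for the simulated cohort."""

    age_mean: float = 69.18
    age_sd: float = 5.73
    age_range: tuple[float, float] = (53.0, 86.0)
    p_female: float = 0.664
    p_tertiary: float = 0.493
    p_in_labor_force: float = 0.145
    pf_mean: float = 79.77
    pf_sd: float = 20.46


@dataclass(frozen=True)
class TrueParameters:
    """Full generative specification of the outcome model (= ground truth)."""

    design: DesignSpec
    beta: dict                      # design column name -> coefficient
    tau: float                      # random-intercept SD
    sigma: float                    # residual SD
    alpha: float = 0.0              # skew-normal shape (0 = normal family)
    outcome_moments: tuple[float, float] = (0.0, 1.0)   # raw-scale (M, SD)
    scale_bounds: tuple[float, float] = (-np.inf, np.inf)  # storage clipping

    def __post_init__(self):
        if self.tau < 0 or self.sigma <= 0:
            raise ValueError("tau must be >= 0 and sigma > 0")
        missing = set(self.design.column_names) - set(self.beta)
        if missing:
            raise ValueError(f"beta missing coefficients for {sorted(missing)}")

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[c] for c in self.design.column_names])

    @property
    def censor_bounds_z(self) -> tuple[float, float]:
        """Modeled censoring bounds on the standardized outcome scale."""
        m, sd = self.outcome_moments
        lo, hi = self.design.raw_bounds
        return (lo - m) / sd, (hi - m) / sd

    def to_json(self, path) -> None:
        d = asdict(self)
        d["design"] = self.design.name
        d["design_columns"] = self.design.column_names
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=float)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design conditions for the generator."""

    n_persons: int = 152
    n_days: int = 10
    completion_prob: float = 0.833
    weekend_days: tuple[int, ...] = (5, 6)
    gains: AarcComponents = AarcComponents(20.95, 2.2690, 1.31)
    losses: AarcComponents = AarcComponents(10.13, 2.8344, 1.5491)
    stressors: StressorModel = StressorModel()
    covariates: CovariateModel = CovariateModel()
    outcome_model: TrueParameters | None = None
    clip_aarc: bool = True

    def __post_init__(self):
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if not 0 < self.completion_prob <= 1:
            raise ValueError("completion_prob must be in (0, 1]")


# ---------------------------------------------------------------------------

def simulate_persons(config: GeneratorConfig, rng: np.random.Generator):
    """Baseline covariates plus person random intercepts u_j ~ Normal(0, tau)."""
    cov = config.covariates
    n = config.n_persons
    lo, hi = cov.age_range
    # truncated normal ages via rejection (cheap at these sizes)
    age = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(cov.age_mean, cov.age_sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        age[todo[ok]] = draw[ok]
        todo = todo[~ok]
    baselines = pd.DataFrame(
        {
            "person_id": [f"p{j:04d}" for j in range(n)],
            "age": np.round(age),
            "gender": (rng.uniform(size=n) < cov.p_female).astype(int),
            "tertiary_educated": (rng.uniform(size=n) < cov.p_tertiary).astype(int),
            "in_labor_force": (rng.uniform(size=n) < cov.p_in_labor_force).astype(int),
            "physical_functioning": np.clip(
                rng.normal(cov.pf_mean, cov.pf_sd, n), 0.0, 100.0
            ),
        }
    )
    tau = config.outcome_model.tau if config.outcome_model is not None else 0.0
    u = tau * rng.standard_normal(n) if tau > 0 else np.zeros(n)
    return baselines, u


def simulate_aarc(config: GeneratorConfig, rng: np.random.Generator):
    """Per-occasion AARC gains/losses as person mean + daily deviation.

    Values are clipped to the scale range [5, 25] when ``config.clip_aarc``;
    the achieved clipping rate is returned alongside the arrays.
    """
    shape = (config.n_persons, config.n_days)
    out = {}
    rates = {}
    for name, comp in (("gains", config.gains), ("losses", config.losses)):
        person_mean = rng.normal(comp.bp_mean, comp.bp_sd, config.n_persons)
        dev = comp.wp_sd * rng.standard_normal(shape)
        vals = person_mean[:, None] + dev
        if config.clip_aarc:
            clipped = np.clip(vals, 5.0, 25.0)
            rates[name] = float(np.mean(clipped != vals))
            vals = clipped
        else:
            rates[name] = 0.0
        out[name] = vals
    return out["gains"], out["losses"], rates


def simulate_aarc_items(total_scores: np.ndarray, rng: np.random.Generator):
    """Item responses (5 items, 1-5) whose sums equal the rounded scale scores.

    Used only to exercise the scoring operations; the outcome models consume
    scale scores directly.
    """
    totals = np.clip(np.rint(np.asarray(total_scores, dtype=float)), 5, 25).astype(int)
    items = np.empty(totals.shape + (5,), dtype=int)
    flat = totals.reshape(-1)
    out = items.reshape(-1, 5)
    for r, t in enumerate(flat):
        row = np.full(5, t // 5)
        rem = t - row.sum()
        bump = rng.choice(5, size=abs(rem), replace=False)
        row[bump] += np.sign(rem)
        # keep within 1..5 (can only leave range when t % 5 != 0 at the edges)
        while row.max() > 5:
            i = row.argmax()
            j = row.argmin()
            row[i] -= 1
            row[j] += 1
        while row.min() < 1:
            i = row.argmin()
            j = row.argmax()
            row[i] += 1
            row[j] -= 1
        out[r] = row
    return items


def simulate_stressors(config: GeneratorConfig, rng: np.random.Generator):
    """Endorsements, severities and the daily stress-severity index."""
    s = config.stressors
    shape = (config.n_persons, config.n_days, N_STRESSORS)
    endorsed = (rng.uniform(size=shape) < s.exposure_prob).astype(int)
    sev = rng.choice(np.arange(1, 6), size=shape, p=s.severity_probs).astype(float)
    sev[endorsed == 0] = np.nan
    index = np.nansum(np.where(endorsed == 1, sev, 0.0), axis=2).astype(int)
    return endorsed, sev, index


def apply_missingness(frame: pd.DataFrame, completion_prob: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Drop occasions iid Bernoulli, guaranteeing >= 1 occasion per person."""
    if not 0 < completion_prob <= 1:
        raise ValueError("completion_prob must be in (0, 1]")
    keep = np.ones(len(frame), dtype=bool)
    if completion_prob < 1:
        keep = rng.uniform(size=len(frame)) < completion_prob
        for pid, idx in frame.groupby("person_id", sort=False).indices.items():
            while not keep[idx].any():
                keep[idx] = rng.uniform(size=len(idx)) < completion_prob
    return frame.loc[keep].reset_index(drop=True)


def simulate_outcome(frame: ModelFrame, params: TrueParameters, u: np.ndarray,
                     rng: np.random.Generator):
    """Standardized censored outcome for a prepared model frame.

    y* = X beta + u_person + e, e ~ skew-normal(mean 0, sd sigma, shape
    alpha); observed y is y* censored at the modeled bounds.  Returns
    (y, censor_code).
    """
    lo, hi = params.censor_bounds_z
    eps = skewnorm.rvs(0.0, params.sigma, params.alpha, frame.n_obs, rng)
    y_latent = frame.X @ params.beta_vector + u[frame.person_index] + eps
    y = np.clip(y_latent, lo, hi)
    censor = np.zeros(frame.n_obs, dtype=int)
    censor[y_latent <= lo] = -1
    censor[y_latent >= hi] = 1
    return y, censor


_OUTCOME_FILLERS = {
    # unconditional filler moments for outcome columns not being modeled
    "negative_affect": (2.50, 1.28, 1.0, 5.0),
    "positive_affect": (3.70, 0.80, 1.0, 5.0),
    "vitality": (4.66, 1.36, 1.0, 7.0),
}


def simulate_dataset(config: GeneratorConfig, seed: int):
    """Full generator: returns (DiaryTable, TrueParameters).

    Deterministic given (config, seed).  The outcome named by
    ``config.outcome_model.design`` is generated from the two-level censored
    model; remaining outcome columns receive unconditional filler draws so
    the table is schema-complete.
    """
    if config.outcome_model is None:
        raise ValueError("config.outcome_model must be set")
    params = config.outcome_model
    rng = np.random.default_rng(seed)

    baselines, u = simulate_persons(config, rng)
    gains, losses, _ = simulate_aarc(config, rng)
    endorsed, sev, stress_idx = simulate_stressors(config, rng)

    n, d = config.n_persons, config.n_days
    person_rep = np.repeat(np.arange(n), d)
    day = np.tile(np.arange(d), n)
    rows = {
        "person_id": baselines["person_id"].to_numpy()[person_rep],
        "day_index": day,
        "is_weekend": np.isin(day, config.weekend_days).astype(int),
        "aarc_gains": gains.reshape(-1),
        "aarc_losses": losses.reshape(-1),
        "stress_severity": stress_idx.reshape(-1),
    }
    for i in range(N_STRESSORS):
        rows[f"s{i + 1}"] = endorsed[:, :, i].reshape(-1)
        rows[f"sev{i + 1}"] = sev[:, :, i].reshape(-1)
    for col in baselines.columns:
        if col != "person_id":
            rows[col] = baselines[col].to_numpy()[person_rep]

    outcome = params.design.outcome
    for col, (m, s, lo, hi) in _OUTCOME_FILLERS.items():
        rows[col] = np.clip(rng.normal(m, s, n * d), lo, hi)
    full = pd.DataFrame(rows)
    full = apply_missingness(full, config.completion_prob, rng)

    # build the predictor matrix on the observed occasions (the outcome
    # column still holds in-range filler values and is replaced below)
    if outcome not in full.columns:   # affect_balance
        full[outcome] = 0.0
    frame = build_model_frame(
        DiaryTable(_complete_columns(full)), params.design,
        outcome_moments=params.outcome_moments,
    )
    y_z, _ = simulate_outcome(frame, params, u, rng)
    m, sd = params.outcome_moments
    y_raw = y_z * sd + m
    lo, hi = params.scale_bounds
    full[outcome] = np.clip(y_raw, lo, hi)

    if outcome == "negative_affect":
        full["affect_balance"] = full["positive_affect"] - full["negative_affect"]
    elif outcome == "affect_balance":
        full["negative_affect"] = np.nan
        full["positive_affect"] = np.nan

    table = DiaryTable(_complete_columns(full))
    return table, params


def _complete_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "affect_balance" not in out.columns or out["affect_balance"].isna().all():
        if {"positive_affect", "negative_affect"} <= set(out.columns):
            with np.errstate(invalid="ignore"):
                out["affect_balance"] = out["positive_affect"] - out["negative_affect"]
    for c in ALL_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    return out[ALL_COLUMNS]
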