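"""Build model frames from diary tables.

The analysis operates on a :class:`ModelFrame`: a standardized outcome with
censoring codes, a named predictor matrix, and a row-to-person index.  The
pipeline applied by :func:`build_model_frame` is, in order:

1. listwise-delete occasions with any missing model variable;
2. split the time-varying predictors into between-person (person-mean) and
   within-person (deviation from person mean) components;
3. standardize continuous variables to the pooled long-form sample
   (disaggregated variables are standardized *before* splitting, so the BP
   and WP columns are components of a unit-variance variable and sum to it);
4. form interaction products from the standardized WP columns (products are
   not re-standardized);
5. code binary predictors -1/+1;
6. flag outcome values lying exactly at a censoring bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DiaryTable

__all__ = [
    "BinaryCovariate",
    "DesignSpec",
    "ModelFrame",
    "person_disaggregate",
    "standardize_long",
    "code_binary",
    "build_time_covariates",
    "transform_bounds",
    "build_model_frame",
]


@dataclass(frozen=True)
class BinaryCovariate:
    """A two-level predictor coded -1/+1 (``positive_value`` maps to +1)."""

    name: str
    source: str
    positive_value: int


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of one model's outcome and predictor set."""

    name: str
    outcome: str
    family: str  # "censored_normal" | "censored_skew_normal"
    raw_bounds: tuple[float, float]
    continuous_covariates: tuple[str, ...] = ("age", "physical_functioning")
    binary_covariates: tuple[BinaryCovariate, ...] = (
        BinaryCovariate("female", "gender", 1),
        BinaryCovariate("tertiary_educated", "tertiary_educated", 1),
        BinaryCovariate("not_in_labor_force", "in_labor_force", 0),
    )
    include_time: bool = True
    weekend: BinaryCovariate | None = BinaryCovariate("weekend", "is_weekend", 1)
    disaggregated: tuple[str, ...] = ("aarc_gains", "aarc_losses", "stress_severity")
    products: tuple[tuple[str, ...], ...] = ()
    rope_main: tuple[str, ...] = ()
    rope_interaction: tuple[str, ...] = ()

    def __post_init__(self):
        if self.family not in ("censored_normal", "censored_skew_normal"):
            raise ValueError(f"unknown family {self.family!r}")
        lo, hi = self.raw_bounds
        if not lo < hi:
            raise ValueError("raw_bounds must satisfy lower < upper")
        wp_cols = {f"wp_{c}" for c in self.disaggregated}
        for prod in self.products:
            base = {p.split("^")[0] for p in prod}
            unknown = base - wp_cols - {f"bp_{c}" for c in self.disaggregated}
            if unknown:
                raise ValueError(f"product references unknown columns {unknown}")

    @property
    def column_names(self) -> list[str]:
        """Predictor-matrix column names in reporting order.

        Age precedes the binary covariates; the remaining continuous
        covariates follow them — the published table layout.
        """
        cols = ["intercept"]
        if "age" in self.continuous_covariates:
            cols.append("age")
        cols += [b.name for b in self.binary_covariates]
        cols += [c for c in self.continuous_covariates if c != "age"]
        if self.include_time:
            cols += ["day", "day_sq"]
        if self.weekend is not None:
            cols.append(self.weekend.name)
        cols += [f"bp_{c}" for c in self.disaggregated]
        cols += [f"wp_{c}" for c in self.disaggregated]
        cols += [product_name(p) for p in self.products]
        return cols

    def with_quadratic_stress(self) -> "DesignSpec":
        """Augmented design with quadratic stress terms and their moderations."""
        extra = (
            ("bp_stress_severity", "bp_stress_severity"),
            ("wp_stress_severity", "wp_stress_severity"),
            ("wp_aarc_gains", "wp_stress_severity", "wp_stress_severity"),
            ("wp_aarc_losses", "wp_stress_severity", "wp_stress_severity"),
        )
        names = tuple(product_name(p) for p in extra[1:])
        return replace(
            self,
            name=self.name + "_quadratic",
            products=self.products + extra,
            rope_interaction=self.rope_interaction + names,
        )


def product_name(parts: Sequence[str]) -> str:
    """Canonical name for an interaction/quadratic product column."""
    out, seen = [], {}
    for p in parts:
        seen[p] = seen.get(p, 0) + 1
    for p in dict.fromkeys(parts):
        out.append(p if seen[p] == 1 else f"{p}^{seen[p]}")
    return ":".join(out)


@dataclass
class ModelFrame:
    """Model-ready arrays for one design on one dataset."""

    y: np.ndarray                    # standardized outcome
    censor_code: np.ndarray          # -1 left-censored, 0 observed, +1 right-censored
    X: np.ndarray                    # (n rows, p predictors)
    columns: list[str]
    person_index: np.ndarray         # row -> 0..J-1
    person_ids: list
    standardization: dict            # variable -> (M, SD)
    bounds: tuple[float, float]      # standardized censoring bounds
    design: DesignSpec
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "person_id", [self.person_ids[i] for i in self.person_index])
        df["y"] = self.y
        df["censor_code"] = self.censor_code
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def person_disaggregate(x: np.ndarray, person_index: np.ndarray):
    """Split a long vector into person-mean (BP) and deviation (WP) parts.

    ``bp + wp`` reconstructs ``x`` exactly; within each person the WP values
    sum to zero over that person's available occasions.
    """
    x = np.asarray(x, dtype=float)
    person_index = np.asarray(person_index)
    if np.any(~np.isfinite(x)):
        raise ValueError("person_disaggregate requires complete data")
    n_persons = person_index.max() + 1
    sums = np.bincount(person_index, weights=x, minlength=n_persons)
    counts = np.bincount(person_index, minlength=n_persons)
    if np.any(counts == 0):
        raise ValueError("person with no observations in person_index")
    means = sums / counts
    bp = means[person_index]
    return bp, x - bp


def standardize_long(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize on the pooled long-form sample (population-SD convention)."""
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance variable")
    return (x - m) / sd, m, sd


def code_binary(x: np.ndarray, positive_value=None):
    """Code a two-level variable -1/+1; returns (codes, mapping)."""
    x = np.asarray(x)
    levels = sorted(pd.unique(x).tolist())
    if len(levels) != 2:
        raise ValueError(f"binary coding needs exactly two levels, got {levels}")
    if positive_value is None:
        positive_value = levels[1]
    if positive_value not in levels:
        raise ValueError(f"positive_value {positive_value!r} not among levels {levels}")
    negative = levels[0] if levels[1] == positive_value else levels[1]
    codes = np.where(x == positive_value, 1.0, -1.0)
    return codes, {negative: -1, positive_value: 1}


def build_time_covariates(day_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw linear and quadratic study-day terms (day coded 0-9)."""
    day = np.asarray(day_index, dtype=float)
    return day, day**2


def transform_bounds(raw_bounds, m: float, sd: float) -> tuple[float, float]:
    """Map raw-scale censoring bounds onto the standardized outcome scale."""
    lo, hi = raw_bounds
    return (lo - m) / sd, (hi - m) / sd


# ---------------------------------------------------------------------------
# frame assembly
# ---------------------------------------------------------------------------

def build_model_frame(
    table: DiaryTable,
    design: DesignSpec,
    outcome_moments: tuple[float, float] | None = None,
) -> ModelFrame:
    """Assemble the model frame for ``design`` from a scored diary table.

    ``outcome_moments`` overrides the sample (M, SD) used to standardize the
    outcome and its censoring bounds — used when fitting simulated data whose
    generative standardization is known exactly.
    """
    df = table.frame
    needed = (
        [design.outcome, "day_index"]
        + list(design.continuous_covariates)
        + [b.source for b in design.binary_covariates]
        + ([design.weekend.source] if design.weekend else [])
        + list(design.disaggregated)
    )
    complete = df[sorted(set(needed))].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    df = df.loc[complete].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no complete occasions left after listwise deletion")

    person_ids = list(dict.fromkeys(df["person_id"]))
    pid_map = {p: i for i, p in enumerate(person_ids)}
    person_index = df["person_id"].map(pid_map).to_numpy()

    standardization: dict = {}
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}

    for c in design.continuous_covariates:
        z, m, sd = standardize_long(df[c].to_numpy())
        cols[c] = z
        standardization[c] = (m, sd)

    for b in design.binary_covariates:
        cols[b.name], mapping = code_binary(df[b.source].to_numpy(), b.positive_value)
        standardization[b.name] = mapping

    if design.include_time:
        day, day_sq = build_time_covariates(df["day_index"].to_numpy())
        for name, v in (("day", day), ("day_sq", day_sq)):
            z, m, sd = standardize_long(v)
            cols[name] = z
            standardization[name] = (m, sd)

    if design.weekend is not None:
        w = design.weekend
        cols[w.name], mapping = code_binary(df[w.source].to_numpy(), w.positive_value)
        standardization[w.name] = mapping

    for c in design.disaggregated:
        z, m, sd = standardize_long(df[c].to_numpy())
        standardization[c] = (m, sd)
        bp, wp = person_disaggregate(z, person_index)
        cols[f"bp_{c}"] = bp
        cols[f"wp_{c}"] = wp

    for prod in design.products:
        v = np.ones(len(df))
        for p in prod:
            v = v * cols[p]
        cols[product_name(prod)] = v

    names = design.column_names
    X = np.column_stack([cols[n] for n in names])

    y_raw = df[design.outcome].to_numpy(dtype=float)
    if outcome_moments is None:
        _, m_y, sd_y = standardize_long(y_raw)
    else:
        m_y, sd_y = outcome_moments
        if sd_y <= 0:
            raise ValueError("outcome SD must be > 0")
    y = (y_raw - m_y) / sd_y
    standardization[design.outcome] = (m_y, sd_y)
    lo_z, hi_z = transform_bounds(design.raw_bounds, m_y, sd_y)

    censor = np.zeros(len(y), dtype=int)
    censor[np.isclose(y, lo_z)] = -1
    censor[np.isclose(y, hi_z)] = 1
    if np.any((y < lo_z) & (censor == 0)) or np.any((y > hi_z) & (censor == 0)):
        raise ValueError("outcome values outside the censoring bounds")

    return ModelFrame(
        y=y,
        censor_code=censor,
        X=X,
        columns=names,
        person_index=person_index,
        person_ids=person_ids,
        standardization=standardization,
        bounds=(lo_z, hi_z),
        design=design,
        n_dropped=n_dropped,
    )
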