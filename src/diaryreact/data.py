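"""Domain types and long-form CSV I/O for daily-diary data.

The interchange object is :class:`DiaryTable`: one row per completed
person-day, carrying scored scales, the five stressor endorsements and
severities, and the person-level baseline covariates repeated on every row.
Missing occasions are simply absent (no placeholder rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .scales import N_STRESSORS

__all__ = [
    "PersonBaseline",
    "DiaryObservation",
    "DiaryTable",
    "DiaryDataError",
    "read_long_csv",
    "write_long_csv",
    "BASELINE_COLUMNS",
    "DIARY_COLUMNS",
    "ALL_COLUMNS",
]


class DiaryDataError(ValueError):
    """Raised for malformed diary tables or CSV files."""


BASELINE_COLUMNS = [
    "age",
    "gender",              # 0 = male, 1 = female (analysis recodes to -1/+1)
    "tertiary_educated",   # 0/1
    "in_labor_force",      # 0/1
    "physical_functioning",
]

STRESSOR_COLUMNS = [f"s{i}" for i in range(1, N_STRESSORS + 1)]
SEVERITY_COLUMNS = [f"sev{i}" for i in range(1, N_STRESSORS + 1)]

DIARY_COLUMNS = [
    "day_index",
    "is_weekend",
    "aarc_gains",
    "aarc_losses",
    "negative_affect",
    "positive_affect",
    "affect_balance",
    "vitality",
    "stress_severity",
    *STRESSOR_COLUMNS,
    *SEVERITY_COLUMNS,
]

ALL_COLUMNS = ["person_id", *DIARY_COLUMNS, *BASELINE_COLUMNS]

_INT_COLUMNS = {"day_index", "is_weekend", "gender", "tertiary_educated",
                "in_labor_force", "stress_severity", *STRESSOR_COLUMNS}

_SCALE_BOUNDS = {
    "aarc_gains": (5, 25),
    "aarc_losses": (5, 25),
    "negative_affect": (1, 5),
    "positive_affect": (1, 5),
    "affect_balance": (-4, 4),
    "vitality": (1, 7),
    "stress_severity": (0, 25),
    "physical_functioning": (0, 100),
}


@dataclass(frozen=True)
class PersonBaseline:
    """Person-level covariates measured at baseline."""

    person_id: str
    age: float
    gender: int                 # 0 = male, 1 = female
    tertiary_educated: int      # 0/1
    in_labor_force: int         # 0/1
    physical_functioning: float # 0-100

    def __post_init__(self) -> None:
        if self.age < 0:
            raise DiaryDataError(f"person {self.person_id}: age must be >= 0")
        if not 0 <= self.physical_functioning <= 100:
            raise DiaryDataError(
                f"person {self.person_id}: physical_functioning must be in [0, 100]"
            )
        for name in ("gender", "tertiary_educated", "in_labor_force"):
            if getattr(self, name) not in (0, 1):
                raise DiaryDataError(f"person {self.person_id}: {name} must be 0/1")


@dataclass(frozen=True)
class DiaryObservation:
    """A single completed evening survey."""

    person_id: str
    day_index: int
    is_weekend: int
    aarc_gains: float
    aarc_losses: float
    negative_affect: float
    positive_affect: float
    vitality: float
    stress_severity: int
    endorsements: tuple[int, ...] = field(default=(0,) * N_STRESSORS)
    severities: tuple[float, ...] = field(default=(np.nan,) * N_STRESSORS)

    @property
    def affect_balance(self) -> float:
        return self.positive_affect - self.negative_affect

    def __post_init__(self) -> None:
        if not 0 <= self.day_index:
            raise DiaryDataError("day_index must be non-negative")
        for name in ("aarc_gains", "aarc_losses", "negative_affect",
                     "positive_affect", "vitality", "stress_severity"):
            lo, hi = _SCALE_BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise DiaryDataError(
                    f"person {self.person_id} day {self.day_index}: "
                    f"{name}={v} outside [{lo}, {hi}]"
                )
        sev_sum = sum(s for e, s in zip(self.endorsements, self.severities) if e == 1)
        if np.isfinite(sev_sum) and sev_sum != self.stress_severity:
            raise DiaryDataError(
                f"person {self.person_id} day {self.day_index}: stress_severity "
                f"{self.stress_severity} != sum of endorsed severities {sev_sum}"
            )


@dataclass
class DiaryTable:
    """Long-form table of diary observations joined to baselines.

    ``frame`` has the columns in :data:`ALL_COLUMNS`, ordered by
    (person_id, day_index), one row per completed occasion.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(
        cls,
        baselines: Iterable[PersonBaseline],
        observations: Iterable[DiaryObservation],
    ) -> "DiaryTable":
        base = {b.person_id: b for b in baselines}
        rows = []
        for o in observations:
            if o.person_id not in base:
                raise DiaryDataError(f"observation for unknown person {o.person_id}")
            b = base[o.person_id]
            row = {
                "person_id": o.person_id,
                "day_index": o.day_index,
                "is_weekend": o.is_weekend,
                "aarc_gains": o.aarc_gains,
                "aarc_losses": o.aarc_losses,
                "negative_affect": o.negative_affect,
                "positive_affect": o.positive_affect,
                "affect_balance": o.affect_balance,
                "vitality": o.vitality,
                "stress_severity": o.stress_severity,
                "age": b.age,
                "gender": b.gender,
                "tertiary_educated": b.tertiary_educated,
                "in_labor_force": b.in_labor_force,
                "physical_functioning": b.physical_functioning,
            }
            for i in range(N_STRESSORS):
                row[f"s{i + 1}"] = o.endorsements[i]
                row[f"sev{i + 1}"] = o.severities[i]
            rows.append(row)
        frame = pd.DataFrame(rows, columns=ALL_COLUMNS)
        frame = frame.sort_values(["person_id", "day_index"], kind="stable")
        return cls(frame)

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        f = self.frame
        missing = [c for c in ALL_COLUMNS if c not in f.columns]
        if missing:
            raise DiaryDataError(f"missing columns: {missing}")
        dup = f.duplicated(subset=["person_id", "day_index"])
        if dup.any():
            pairs = f.loc[dup, ["person_id", "day_index"]].values.tolist()
            raise DiaryDataError(f"duplicate (person, day) pairs: {pairs[:5]}")
        per_person = f.groupby("person_id", sort=False)[BASELINE_COLUMNS].nunique()
        if (per_person > 1).any().any():
            raise DiaryDataError("baseline covariates differ across a person's rows")
        for name, (lo, hi) in _SCALE_BOUNDS.items():
            v = f[name]
            bad = v.notna() & ((v < lo) | (v > hi))
            if bad.any():
                raise DiaryDataError(f"{name} outside [{lo}, {hi}] in {int(bad.sum())} rows")
        sev = f[SEVERITY_COLUMNS].to_numpy(dtype=float)
        end = f[STRESSOR_COLUMNS].to_numpy(dtype=float)
        expected = np.nansum(np.where(end == 1, sev, 0.0), axis=1)
        ok = np.isclose(expected, f["stress_severity"].to_numpy(dtype=float))
        if not ok.all():
            raise DiaryDataError(
                f"stress_severity != sum of endorsed severities in {int((~ok).sum())} rows"
            )

    # -- convenience ---------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.frame["person_id"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)


def write_long_csv(table: DiaryTable, path) -> None:
    """Write a diary table to UTF-8 CSV ('.' decimal separator)."""
    table.frame.to_csv(path, index=False, encoding="utf-8")


def read_long_csv(path) -> DiaryTable:
    """Read a long-form diary CSV written by :func:`write_long_csv`.

    Unknown columns raise a warning and are dropped; unparsable numeric
    values raise :class:`DiaryDataError` naming the offending row.
    """
    raw = pd.read_csv(path, dtype=str, encoding="utf-8", keep_default_na=False)
    unknown = [c for c in raw.columns if c not in ALL_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
        raw = raw.drop(columns=unknown)
    missing = [c for c in ALL_COLUMNS if c not in raw.columns]
    if missing:
        raise DiaryDataError(f"CSV is missing required columns: {missing}")

    out = {}
    out["person_id"] = raw["person_id"].astype(str)
    for col in ALL_COLUMNS:
        if col == "person_id":
            continue
        vals = raw[col].replace("", np.nan)
        num = pd.to_numeric(vals, errors="coerce")
        bad = vals.notna() & num.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DiaryDataError(
                f"unparsable value {vals.iloc[row]!r} in column {col!r}, "
                f"data row {row + 1}"
            )
        if col in _INT_COLUMNS and num.notna().all():
            num = num.astype(np.int64)
        out[col] = num
    frame = pd.DataFrame(out, columns=ALL_COLUMNS)
    return DiaryTable(frame)
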