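"""Scale scoring for the daily-diary instruments.

Scoring conventions are fixed by the instruments' observed ranges:
AARC-gains and AARC-losses are five-item *sum* scores (range 5-25 each),
while affect (SPANE) and vitality are item *means* on their response
scales.  Missing items invalidate the whole scale for that occasion; no
partial-scale imputation is performed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "ScoringError",
    "score_aarc",
    "score_spane",
    "score_vitality",
    "stress_severity_index",
    "recode_physical_functioning",
    "cronbach_alpha",
]

N_STRESSORS = 5


class ScoringError(ValueError):
    """Raised when item responses are missing or out of range."""


def _check_items(items: Sequence, n: int, lo: int, hi: int, what: str) -> np.ndarray:
    arr = np.asarray(items, dtype=float)
    if arr.shape != (n,):
        raise ScoringError(f"{what}: expected exactly {n} item responses, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)):
        raise ScoringError(f"{what}: missing (non-finite) item response")
    if np.any((arr < lo) | (arr > hi)):
        raise ScoringError(f"{what}: item responses must lie in [{lo}, {hi}]")
    return arr


def score_aarc(item_responses: Sequence[int]) -> tuple[float, float]:
    """Score the 10-item short-form awareness-of-age-related-change scale.

    Items are treated positionally: the first five items form the gains
    subscale, the last five the losses subscale.  Each subscale is the sum
    of its items (1-5 response scale), so scores range over [5, 25] with
    higher values indicating more awareness of gains/losses.

    Returns
    -------
    (gains, losses) : tuple of float
    """
    arr = _check_items(item_responses, 10, 1, 5, "AARC")
    gains = float(arr[:5].sum())
    losses = float(arr[5:].sum())
    return gains, losses


def score_spane(item_responses: Sequence[int]) -> tuple[float, float, float]:
    """Score the 12-item positive/negative experience scale.

    The first six items are the negative-feeling items, the last six the
    positive-feeling items (1-5 response scale).  Subscale scores are item
    means in [1, 5]; affect balance is positive minus negative, in [-4, 4].

    Returns
    -------
    (negative_affect, positive_affect, affect_balance)
    """
    arr = _check_items(item_responses, 12, 1, 5, "SPANE")
    na = float(arr[:6].mean())
    pa = float(arr[6:].mean())
    return na, pa, pa - na


def score_vitality(item_responses: Sequence[int]) -> float:
    """Score the six-item subjective vitality scale (1-7) as an item mean."""
    arr = _check_items(item_responses, 6, 1, 7, "vitality")
    return float(arr.mean())


def stress_severity_index(
    endorsements: Sequence[int], severities: Sequence[float | None]
) -> int:
    """Daily stress-severity index: sum of severity ratings over endorsed stressors.

    ``endorsements`` holds five 0/1 flags for the five stressor categories;
    ``severities`` holds the matching 1-5 ratings, with ``None`` (or NaN)
    where the stressor was not endorsed.  Unendorsed stressors contribute 0,
    so a completed day with no stressors scores 0; the index ranges 0-25.

    Raises
    ------
    ScoringError
        If a severity is supplied for an unendorsed stressor, a severity is
        missing for an endorsed one, or any value is out of range.
    """
    end = np.asarray(endorsements)
    if end.shape != (N_STRESSORS,) or not np.isin(end, (0, 1)).all():
        raise ScoringError("endorsements must be five 0/1 flags")
    if len(severities) != N_STRESSORS:
        raise ScoringError("severities must have five entries (None where unendorsed)")
    total = 0
    for i, (e, s) in enumerate(zip(end, severities)):
        missing = s is None or (isinstance(s, float) and np.isnan(s))
        if e == 1:
            if missing:
                raise ScoringError(f"stressor {i + 1} endorsed but severity missing")
            if not (1 <= s <= 5 and float(s).is_integer()):
                raise ScoringError(f"stressor {i + 1} severity must be an integer in 1-5")
            total += int(s)
        elif not missing:
            raise ScoringError(f"severity supplied for unendorsed stressor {i + 1}")
    return total


def recode_physical_functioning(item_responses: Sequence[int]) -> float:
    """Recode the 10-item physical-functioning subscale to a 0-100 score.

    Items are answered on a 3-point scale, 1 = "limited a lot" to
    3 = "not limited at all".  Each item is linearly recoded to
    {0, 50, 100} and the items averaged, the standard convention for this
    health-survey subscale; higher scores mean better functioning.
    """
    arr = _check_items(item_responses, 10, 1, 3, "physical functioning")
    return float(((arr - 1) * 50.0).mean())


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with variances computed with ddof=1 over respondents.

    Parameters
    ----------
    item_matrix : array (n respondents, k items), no missing cells.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("item_matrix must be 2-D with at least 2 items")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 respondents")
    if np.any(~np.isfinite(x)):
        raise ValueError("item_matrix contains missing cells")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
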