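"""Post-fit probing of interactions: reactivity slopes and quadratic curves.

The stress-reactivity slope is the within-person stress-severity
coefficient evaluated at chosen levels of the WP AARC moderators.  With
the three-way design

    slope(g, l) = b_s + b_gs * g + b_ls * l + b_gls * g * l

where g and l are WP gains/losses offsets in SD units.  By default one
"SD unit" is the empirical SD of the standardized WP component column
(which is below 1, since the WP column is a component of a long-form
standardized variable); set ``unit="one"`` to use +-1 on the standardized
scale instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rope import hdi

__all__ = [
    "SlopeGrid",
    "reactivity_slope",
    "slope_differences",
    "quadratic_curve",
]

_GAINS = "wp_aarc_gains"
_LOSSES = "wp_aarc_losses"
_STRESS = "wp_stress_severity"


def _column_sd(fit_result, name: str, unit: str) -> float:
    if unit == "one":
        return 1.0
    if unit != "column_sd":
        raise ValueError("unit must be 'column_sd' or 'one'")
    model = fit_result.model
    if model is None:
        raise ValueError("fit result carries no model frame; use unit='one'")
    return float(model.frame.column(name).std(ddof=0))


def _coef_draws(fit_result, name: str) -> np.ndarray:
    if name not in fit_result.param_names:
        raise KeyError(f"fit has no coefficient {name!r}; was the design fitted?")
    return fit_result.draws(name)


@dataclass
class SlopeGrid:
    """Reactivity-slope draws on a gains x losses grid (SD units)."""

    gains_levels: tuple[float, ...]
    losses_levels: tuple[float, ...]
    draws: dict = field(repr=False)  # (g, l) -> draw vector

    def cell(self, g: float, l: float) -> np.ndarray:
        return self.draws[(g, l)]

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for (g, l), d in self.draws.items():
            lo, hi = hdi(d, mass)
            rows.append(
                {"wp_gains_sd": g, "wp_losses_sd": l,
                 "Est": d.mean(), "Error": d.std(ddof=1), "Low": lo, "High": hi}
            )
        return pd.DataFrame(rows)


def reactivity_slope(
    fit_result,
    g: float,
    l: float,
    unit: str = "column_sd",
) -> np.ndarray:
    """Posterior draws of the WP stress slope at WP gains/losses offsets.

    ``g`` and ``l`` are in SD units of the respective WP columns (see
    module docstring for the unit convention).
    """
    b_s = _coef_draws(fit_result, _STRESS)
    b_gs = _coef_draws(fit_result, f"{_GAINS}:{_STRESS}")
    b_ls = _coef_draws(fit_result, f"{_LOSSES}:{_STRESS}")
    b_gls = _coef_draws(fit_result, f"{_GAINS}:{_LOSSES}:{_STRESS}")
    gv = g * _column_sd(fit_result, _GAINS, unit)
    lv = l * _column_sd(fit_result, _LOSSES, unit)
    return b_s + b_gs * gv + b_ls * lv + b_gls * gv * lv


def slope_grid(
    fit_result,
    gains_levels=(-1.0, 1.0),
    losses_levels=(-1.0, 1.0),
    unit: str = "column_sd",
) -> SlopeGrid:
    draws = {
        (g, l): reactivity_slope(fit_result, g, l, unit)
        for g in gains_levels
        for l in losses_levels
    }
    return SlopeGrid(tuple(gains_levels), tuple(losses_levels), draws)


def slope_differences(fit_result, unit: str = "column_sd") -> pd.DataFrame:
    """Low-minus-high-gains slope differences by losses level, and their difference.

    The difference-of-differences equals 4 * sd_g * sd_l * b_gls draw by
    draw (4 * b_gls when unit='one'), i.e. the effect size of the three-way
    interaction.
    """
    grid = slope_grid(fit_result, (-1.0, 1.0), (-1.0, 1.0), unit)
    diff_low = grid.cell(-1.0, -1.0) - grid.cell(1.0, -1.0)   # low - high gains
    diff_high = grid.cell(-1.0, 1.0) - grid.cell(1.0, 1.0)
    # oriented so that it equals +4 sd_g sd_l b_gls draw by draw
    dod = diff_low - diff_high
    return pd.DataFrame(
        {
            "low_gains_minus_high_gains_at_low_losses": diff_low,
            "low_gains_minus_high_gains_at_high_losses": diff_high,
            "difference_of_differences": dod,
        }
    )


def quadratic_curve(
    fit_result,
    l: float,
    stress_grid: np.ndarray,
    unit: str = "column_sd",
    mass: float = 0.95,
) -> pd.DataFrame:
    """Expected-outcome curve over WP stress at a WP losses level.

    Evaluates, per draw, the partial linear predictor

        eta(s) = b_s s + b_s2 s^2 + b_l l + b_ls l s + b_ls2 l s^2

    on ``stress_grid`` (standardized WP stress scale), other predictors at
    zero; returns posterior mean and HDI band per grid point.
    """
    s = np.asarray(stress_grid, dtype=float)
    lv = l * _column_sd(fit_result, _LOSSES, unit)
    b_s = _coef_draws(fit_result, _STRESS)
    b_s2 = _coef_draws(fit_result, f"{_STRESS}^2")
    b_l = _coef_draws(fit_result, _LOSSES)
    b_ls = _coef_draws(fit_result, f"{_LOSSES}:{_STRESS}")
    b_ls2 = _coef_draws(fit_result, f"{_LOSSES}:{_STRESS}^2")
    # draws x grid
    eta = (
        np.outer(b_s, s)
        + np.outer(b_s2, s**2)
        + b_l[:, None] * lv
        + np.outer(b_ls, s) * lv
        + np.outer(b_ls2, s**2) * lv
    )
    rows = []
    for j, sj in enumerate(s):
        lo, hi = hdi(eta[:, j], mass)
        rows.append({"wp_stress": sj, "Est": eta[:, j].mean(), "Low": lo, "High": hi})
    return pd.DataFrame(rows)
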