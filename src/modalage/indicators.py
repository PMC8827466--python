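"""Old-age mortality indicators from a smooth age-at-death distribution.

From the continuous survival S(x) and density f(x) = mu(x) S(x) of one
stratum-year this module extracts

* the modal age at death M — the argmax of f above a search floor, refined
  to sub-grid precision by quadratic interpolation;
* SD(M+) — root-mean-square deviation of ages at death above M, measured
  from M itself (the Kannisto convention), a compression measure;
* conditional life expectancies on the attained-age convention,
  e_x = x + E[remaining life | alive at x], so e_75 >= e_65 by design;
* proportions of those alive at the radix age surviving to M, 65 and 75;
* the age at which survival crosses a given probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .curves import SmoothHazard, survival_and_density  # noqa: F401  (re-export)
from .psplines import SmoothFit, evaluate_hazard

__all__ = [
    "SmoothHazard",
    "survival_and_density",
    "ModeEstimate",
    "IndicatorSet",
    "modal_age",
    "sd_above_mode",
    "conditional_attained_expectancy",
    "proportion_surviving",
    "age_at_survival_quantile",
    "compute_indicators",
    "indicator_trends",
]

#: Default lower bound of the mode search, safely above the grid start and
#: below any plausible adult mode; excludes residual young-adult humps.
DEFAULT_MODE_FLOOR = 45.0


class ModeEstimate(NamedTuple):
    age: float
    at_boundary: bool


def modal_age(sh: SmoothHazard, floor: float = DEFAULT_MODE_FLOOR) -> ModeEstimate:
    """Locate the modal age at death on [floor, grid end].

    The discrete argmax (ties broken toward the older age) is refined by a
    parabola through the three surrounding grid points.  A maximum sitting
    on the search floor or the upper grid end is returned flagged rather
    than silently: such a mode is not interior and not trustworthy.
    """
    if floor < sh.ages[0]:
        raise ValueError("search floor below the grid start")
    mask = sh.ages >= floor
    x = sh.ages[mask]
    f = sh.density[mask]
    # last occurrence of the maximum = tie toward the older age
    j = len(f) - 1 - int(np.argmax(f[::-1]))
    if j == 0 or j == len(f) - 1:
        return ModeEstimate(age=float(x[j]), at_boundary=True)
    denom = f[j - 1] - 2.0 * f[j] + f[j + 1]
    if denom >= 0 or abs(denom) < 1e-300:
        return ModeEstimate(age=float(x[j]), at_boundary=False)
    offset = 0.5 * (f[j - 1] - f[j + 1]) / denom
    return ModeEstimate(age=float(x[j] + offset * sh.step), at_boundary=False)


def _upper_segment(sh: SmoothHazard, x0: float, values: np.ndarray):
    """Grid restricted to [x0, end], with the left endpoint interpolated."""
    idx = int(np.searchsorted(sh.ages, x0, side="right"))
    xs = np.concatenate(([x0], sh.ages[idx:]))
    vs = np.concatenate(([np.interp(x0, sh.ages, values)], values[idx:]))
    return xs, vs


def sd_above_mode(sh: SmoothHazard, m: float) -> float:
    """SD(M+): sqrt( int_M (x-M)^2 f dx / int_M f dx )."""
    if not (sh.ages[0] < m < sh.ages[-1]):
        raise ValueError("mode must be interior to the age grid")
    xs, fs = _upper_segment(sh, m, sh.density)
    mass = trapezoid(fs, xs)
    if mass < 1e-6:
        raise ValueError("negligible death mass above the mode")
    return float(np.sqrt(trapezoid((xs - m) ** 2 * fs, xs) / mass))


def conditional_attained_expectancy(sh: SmoothHazard, x: float) -> float:
    """Average attained age at death among survivors to ``x``:
    e_x = x + (1/S(x)) int_x S(t) dt, with the grid end a hard endpoint."""
    if not (sh.ages[0] <= x < sh.ages[-1]):
        raise ValueError("threshold outside the age grid")
    s_x = sh.interp_survival(x)
    if s_x < 1e-10:
        raise ValueError("survival at threshold is numerically zero")
    xs, ss = _upper_segment(sh, x, sh.survival)
    return float(x + trapezoid(ss, xs) / s_x)


def proportion_surviving(sh: SmoothHazard, target: float) -> float:
    """Proportion of those alive at the radix age surviving to ``target``."""
    if not (sh.ages[0] <= target <= sh.ages[-1]):
        raise ValueError("target age outside the grid")
    return sh.interp_survival(target)


def age_at_survival_quantile(sh: SmoothHazard, p: float) -> float:
    """The age at which survival crosses probability ``p``."""
    if not (sh.survival[-1] < p < 1.0):
        raise ValueError(
            f"p must lie in (S(end), 1) = ({sh.survival[-1]:.3g}, 1), got {p}"
        )
    # survival is nonincreasing; interpolate on the reversed curve
    return float(np.interp(p, sh.survival[::-1], sh.ages[::-1]))


@dataclass
class IndicatorSet:
    """All indicators for one stratum-year."""

    stratum: str
    year: int
    M: float
    mode_flagged: bool
    sd_above_M: float
    e65: float
    e75: float
    p_surv_M: float
    p_surv_65: float
    p_surv_75: float
    quantile_p: float
    age_at_quantile: float


def compute_indicators(
    sh: SmoothHazard,
    mode_floor: float = DEFAULT_MODE_FLOOR,
    thresholds: tuple[float, float] = (65.0, 75.0),
    quantile_p: float = 0.80,
) -> IndicatorSet:
    mode = modal_age(sh, floor=mode_floor)
    t_lo, t_hi = thresholds
    sd = np.nan
    if not mode.at_boundary:
        sd = sd_above_mode(sh, mode.age)
    return IndicatorSet(
        stratum=sh.stratum or "",
        year=int(sh.year) if sh.year is not None else 0,
        M=mode.age,
        mode_flagged=mode.at_boundary,
        sd_above_M=sd,
        e65=conditional_attained_expectancy(sh, t_lo),
        e75=conditional_attained_expectancy(sh, t_hi),
        p_surv_M=proportion_surviving(sh, mode.age),
        p_surv_65=proportion_surviving(sh, t_lo),
        p_surv_75=proportion_surviving(sh, t_hi),
        quantile_p=quantile_p,
        age_at_quantile=age_at_survival_quantile(sh, quantile_p),
    )


GAP_COLUMNS = ("M", "sd_above_M", "e65", "e75", "p_surv_65", "p_surv_75")


def indicator_trends(
    fits: Iterable[SmoothFit],
    years: Iterable[int] | None = None,
    reference_class: str | None = "upper_nonmanual",
    grid_step: float = 0.01,
    mode_floor: float = DEFAULT_MODE_FLOOR,
    thresholds: tuple[float, float] = (65.0, 75.0),
    quantile_p: float = 0.80,
) -> pd.DataFrame:
    """Tabulate indicators for every stratum-year covered by the fits.

    Gap columns (``<name>_gap``) hold the reference class's value minus the
    stratum's own, computed within sex and year, so a positive modal-age
    gap reads "the reference class outlives this one".  Rows whose mode sat
    on a search boundary are flagged and excluded from gaps with a warning.
    """
    rows = []
    for fit in fits:
        fit_years = fit.years if years is None else [y for y in years if y in fit.years]
        for y in fit_years:
            sh = evaluate_hazard(fit, int(y), step=grid_step)
            ind = compute_indicators(
                sh, mode_floor=mode_floor, thresholds=thresholds, quantile_p=quantile_p
            )
            rows.append(vars(ind).copy())
    table = pd.DataFrame(rows).sort_values(["stratum", "year"]).reset_index(drop=True)
    if table["mode_flagged"].any():
        n_bad = int(table["mode_flagged"].sum())
        warnings.warn(
            f"{n_bad} stratum-year(s) have boundary modes; excluded from gap columns",
            stacklevel=2,
        )
    if reference_class is not None:
        parts = table["stratum"].str.partition(":")
        table["sex"] = parts[0]
        table["class"] = parts[2]
        ref = table[(table["class"] == reference_class) & ~table["mode_flagged"]]
        ref = ref.set_index(["sex", "year"])
        for col in GAP_COLUMNS:
            ref_vals = table.set_index(["sex", "year"]).index.map(ref[col].to_dict())
            gap = np.asarray(ref_vals, dtype=float) - table[col].to_numpy()
            gap[table["mode_flagged"].to_numpy()] = np.nan
            table[f"{col}_gap"] = gap
    return table
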