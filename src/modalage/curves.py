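"""Continuous survival and age-at-death density derived from a hazard.

Given a strictly positive force of mortality mu(x) on a fine, uniform age
grid starting at the radix age, survival is S(x) = exp(-int mu) by
cumulative trapezoidal integration and the age-at-death density is
f(x) = mu(x) S(x).  All life-table indicators downstream are integrals or
extrema of these two curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = ["SmoothHazard", "survival_and_density"]


@dataclass
class SmoothHazard:
    """Hazard, survival and density for one stratum-year on a fine grid.

    The survival radix is the first grid age (S = 1 there), so survival
    values read as proportions of those alive at the grid start.
    """

    ages: np.ndarray
    hazard: np.ndarray
    survival: np.ndarray
    density: np.ndarray
    stratum: str | None = None
    year: int | None = None

    @property
    def step(self) -> float:
        return float(self.ages[1] - self.ages[0])

    def interp_survival(self, x: float) -> float:
        return float(np.interp(x, self.ages, self.survival))

    def interp_density(self, x: float) -> float:
        return float(np.interp(x, self.ages, self.density))

    def validate(self) -> None:
        if np.any(self.hazard <= 0):
            raise ValueError("hazard must be strictly positive")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")
        total = trapezoid(self.density, self.ages) + self.survival[-1]
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"density + right-tail survival integrate to {total}, not 1")


def survival_and_density(
    ages: np.ndarray,
    hazard: np.ndarray,
    stratum: str | None = None,
    year: int | None = None,
) -> SmoothHazard:
    """Complete a hazard curve into a :class:`SmoothHazard`.

    ``ages`` must be a uniform fine grid (step <= 0.01 recommended) and
    ``hazard`` strictly positive everywhere on it.
    """
    ages = np.asarray(ages, dtype=float)
    hazard = np.asarray(hazard, dtype=float)
    if ages.ndim != 1 or ages.shape != hazard.shape:
        raise ValueError("ages and hazard must be matching 1-D arrays")
    steps = np.diff(ages)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8):
        raise ValueError("age grid must be uniform and increasing")
    if np.any(hazard <= 0):
        raise ValueError("hazard must be strictly positive everywhere")
    cumhaz = cumulative_trapezoid(hazard, ages, initial=0.0)
    survival = np.exp(-cumhaz)
    density = hazard * survival
    return SmoothHazard(
        ages=ages,
        hazard=hazard,
        survival=survival,
        density=density,
        stratum=stratum,
        year=year,
    )
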