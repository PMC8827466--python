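"""Synthetic stratified mortality surfaces with known ground truth.

Adult mortality in each stratum follows a Gompertz-Makeham hazard

    mu(x, t) = c * (1 - r_c)^(t - t0) + a * (1 - r)^(t - t0) * exp(b * x)

with age ``x``, calendar year ``t`` and reference year ``t0``.  The
proportional annual decline ``r`` in the Gompertz level shifts the modal
age at death upward by ``-log(1 - r) / b`` years per calendar year, which
emulates the near-linear secular rise in the mode seen in register data.
Death counts are Poisson given the hazard and person-years of exposure.

For a pure Gompertz hazard (c = 0) the age-at-death density mu(x)S(x) has
its stationary point at ``(1/b) log(b/a)`` regardless of the radix age, so
every scenario built here carries a closed-form true modal age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import MortalityDataset, Stratum

__all__ = [
    "StratumHazard",
    "ScenarioParams",
    "hazard_surface",
    "sample_deaths",
    "finnish_like_scenario",
    "true_modal_age",
    "gompertz_survival",
]


@dataclass(frozen=True)
class StratumHazard:
    """Gompertz-Makeham parameters for one stratum.

    a : Gompertz level at the reference year (deaths / person-year)
    b : Gompertz slope (per year of age)
    c : Makeham (age-independent) level (deaths / person-year)
    r : proportional annual decline in ``a``  (0 <= r < 1)
    r_c : proportional annual decline in ``c`` (defaults to 0)
    """

    a: float
    b: float
    c: float = 0.0
    r: float = 0.0
    r_c: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Gompertz level a and slope b must be positive")
        if self.c < 0:
            raise ValueError("Makeham level c must be nonnegative")
        if not (0 <= self.r < 1 and 0 <= self.r_c < 1):
            raise ValueError("annual improvement rates must lie in [0, 1)")


@dataclass
class ScenarioParams:
    """A multi-stratum scenario: hazards, grids, exposures and seed.

    ``exposure`` may be a scalar (age-flat person-years per cell) or an
    age-shaped vector matching the age grid.
    """

    hazards: dict[Stratum, StratumHazard]
    age_range: tuple[int, int] = (31, 110)
    year_range: tuple[int, int] = (1971, 2015)
    exposure: float | np.ndarray = 2e4
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        y0, y1 = self.year_range
        if hi - lo + 1 < 10:
            raise ValueError("age grid must span at least 10 single years")
        if y1 - y0 + 1 < 2:
            raise ValueError("year grid must span at least 2 calendar years")
        exp_arr = np.atleast_1d(np.asarray(self.exposure, dtype=float))
        if np.any(exp_arr < 0):
            raise ValueError("exposures must be nonnegative")
        if exp_arr.size not in (1, self.ages.size):
            raise ValueError("exposure must be scalar or one value per age")
        # every stratum must keep its true mode strictly inside the age range
        for s, h in self.hazards.items():
            for year in (y0, y1):
                m = true_modal_age(self, s, year)
                if not (lo < m < hi):
                    raise ValueError(
                        f"true modal age {m:.1f} for {s.label} in {year} "
                        f"falls outside ({lo}, {hi})"
                    )

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_range[0], self.age_range[1] + 1)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)

    def exposure_grid(self) -> np.ndarray:
        """Person-years per age x year cell."""
        e = np.atleast_1d(np.asarray(self.exposure, dtype=float))
        col = np.full(self.ages.size, e[0]) if e.size == 1 else e
        return np.repeat(col[:, None], self.years.size, axis=1)

    def to_meta(self) -> dict:
        return {
            "kind": "synthetic",
            "seed": int(self.seed),
            "age_range": list(self.age_range),
            "year_range": list(self.year_range),
            "hazards": {
                s.label: {"a": float(h.a), "b": float(h.b), "c": float(h.c),
                          "r": float(h.r), "r_c": float(h.r_c)}
                for s, h in self.hazards.items()
            },
            **self.meta,
        }


def hazard_surface(params: ScenarioParams, stratum: Stratum | str) -> np.ndarray:
    """True hazard mu(x, t) on the scenario's age x year grid for one stratum."""
    if isinstance(stratum, str):
        stratum = Stratum.from_label(stratum)
    h = params.hazards[stratum]
    x = params.ages[:, None].astype(float)
    t = (params.years - params.year_range[0])[None, :].astype(float)
    mu = h.c * (1.0 - h.r_c) ** t + h.a * (1.0 - h.r) ** t * np.exp(h.b * x)
    return mu


def true_modal_age(params: ScenarioParams, stratum: Stratum | str, year: int) -> float:
    """Ground-truth modal age at death for one stratum-year.

    Closed form ``(1/b) log(b/a_t)`` for pure Gompertz; otherwise found by
    maximizing mu(x) exp(-int mu) on a 0.001-year grid.
    """
    if isinstance(stratum, str):
        stratum = Stratum.from_label(stratum)
    h = params.hazards[stratum]
    t = year - params.year_range[0]
    a_t = h.a * (1.0 - h.r) ** t
    if h.c == 0.0:
        return np.log(h.b / a_t) / h.b
    c_t = h.c * (1.0 - h.r_c) ** t
    lo, hi = params.age_range
    x = np.arange(lo, hi + 1e-9, 1e-3)
    mu = c_t + a_t * np.exp(h.b * x)
    # cumulative hazard of Makeham has a closed form; use it for accuracy
    cumhaz = c_t * (x - lo) + (a_t / h.b) * (np.exp(h.b * x) - np.exp(h.b * lo))
    f = mu * np.exp(-cumhaz)
    return float(x[np.argmax(f)])


def gompertz_survival(a: float, b: float, x: np.ndarray, radix_age: float = 31.0) -> np.ndarray:
    """Analytic pure-Gompertz survival from ``radix_age``."""
    x = np.asarray(x, dtype=float)
    return np.exp(-(a / b) * (np.exp(b * x) - np.exp(b * radix_age)))


def sample_deaths(
    params: ScenarioParams,
    hazard: dict[Stratum, np.ndarray] | None = None,
    seed: int | None = None,
) -> MortalityDataset:
    """Draw Poisson death counts D ~ Poisson(mu * E) for every stratum.

    ``hazard`` may override the scenario's own surfaces (same grids); the
    dataset retains the true hazard.  Reproducible given the seed.
    """
    seed = params.seed if seed is None else seed
    strata = sorted(params.hazards)
    exp_grid = params.exposure_grid()
    mu = np.stack(
        [hazard[s] if hazard is not None else hazard_surface(params, s) for s in strata]
    )
    if np.any(mu <= 0):
        raise ValueError("hazard must be strictly positive")
    rng = np.random.default_rng(seed)
    expos = np.repeat(exp_grid[None, :, :], len(strata), axis=0)
    deaths = rng.poisson(mu * expos).astype(float)
    return MortalityDataset(
        ages=params.ages,
        years=params.years,
        strata=strata,
        deaths=deaths,
        exposures=expos,
        true_hazard=mu,
        meta=params.to_meta(),
    )


# ---------------------------------------------------------------------------
# The default multi-class scenario

#: Occupational classes in hierarchy order (lowest mortality first).
CLASSES = ("upper_nonmanual", "lower_nonmanual", "manual")


def finnish_like_params(
    n_years: int = 45,
    exposure: float | np.ndarray = 2e4,
    seed: int = 0,
) -> ScenarioParams:
    """Parameters of the default 3-class x 2-sex scenario.

    Calibration: shared within-sex Gompertz slope (males b=0.10, females
    b=0.11); class levels set through a = b exp(-b M0) with reference-year
    modes M0 of 77/75/73.5 (males) and 80/79/78 (females), giving a male
    upper-vs-manual modal-age gap of 3.5 years; equal proportional annual
    improvement within sex (males 1.5 %/yr, females 1.3 %/yr) moves every
    mode up near-linearly by ~0.13-0.15 years per calendar year, from the
    mid-70s into the mid-80s over 45 years.  Survival from 31 to the mode
    is exp(-(1 - (a/b) e^{31 b})), just below 40 % throughout.
    """
    mode_starts = {
        "male": dict(zip(CLASSES, (77.0, 75.0, 73.5))),
        "female": dict(zip(CLASSES, (80.0, 79.0, 78.0))),
    }
    slopes = {"male": 0.10, "female": 0.11}
    improvements = {"male": 0.015, "female": 0.013}
    hazards = {}
    for sex in ("male", "female"):
        b = slopes[sex]
        for klass in CLASSES:
            a = b * np.exp(-b * mode_starts[sex][klass])
            hazards[Stratum(sex, klass)] = StratumHazard(a=a, b=b, r=improvements[sex])
    return ScenarioParams(
        hazards=hazards,
        age_range=(31, 110),
        year_range=(1971, 1971 + n_years - 1),
        exposure=exposure,
        seed=seed,
        meta={"scenario": "finnish_like"},
    )


def finnish_like_scenario(
    seed: int = 0,
    n_years: int = 45,
    exposure: float | np.ndarray = 2e4,
) -> MortalityDataset:
    """Sampled dataset for the default scenario: 6 strata, ages 31-110."""
    params = finnish_like_params(n_years=n_years, exposure=exposure, seed=seed)
    return sample_deaths(params)


def aged_exposure_profile(
    ages: np.ndarray, base: float = 2e4, decline_start: float = 80.0, halving: float = 8.0
) -> np.ndarray:
    """Optional age-shaped exposure: flat, then halving every ``halving``
    years above ``decline_start`` — a crude population pyramid tail."""
    ages = np.asarray(ages, dtype=float)
    excess = np.clip(ages - decline_start, 0.0, None)
    return base * 0.5 ** (excess / halving)
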