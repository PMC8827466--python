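"""Penalized B-spline (P-spline) Poisson smoothing of mortality surfaces.

The log hazard is expanded on a rich equally-spaced B-spline basis (cubic,
5-year knot spacing by default) and fitted to death counts with a
log-exposure offset by iteratively reweighted penalized least squares.  A
difference penalty of order 2 on adjacent coefficients controls
smoothness; its weight lambda is chosen per stratum by minimizing

    BIC = deviance + log(n) * ED,

where n counts cells with positive exposure and ED is the trace of the
influence matrix.  Two-dimensional (age x calendar year) smoothing uses a
tensor-product basis with an additive anisotropic penalty
``lam_age * (P_age kron I) + lam_year * (I kron P_year)``.

The infinite-penalty limit of the order-2 penalty is the log-linear
(Gompertz) GLM fit in 1D and the bilinear log-hazard in 2D, which the test
suite exploits as an analytic oracle.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .curves import SmoothHazard, survival_and_density

__all__ = [
    "BasisSpec",
    "PenaltySpec",
    "SmoothFit",
    "build_basis",
    "build_penalty",
    "fit_1d",
    "fit_2d",
    "select_lambda",
    "evaluate_hazard",
    "default_lambda_grid",
]

#: Default smoothing-weight grid, log10 lambda in -2 .. 6 (per dimension).
DEFAULT_LOG10_LAMBDAS = tuple(range(-2, 7))


def default_lambda_grid() -> np.ndarray:
    return 10.0 ** np.array(DEFAULT_LOG10_LAMBDAS, dtype=float)


@dataclass(frozen=True)
class BasisSpec:
    """Equally-spaced B-spline basis on [lower, upper].

    Knots are spaced ``spacing`` units apart and extended ``degree`` knots
    beyond each end, giving ``ceil((upper - lower)/spacing) + degree``
    basis functions that sum to one at every interior point.
    """

    lower: float
    upper: float
    spacing: float = 5.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError("upper must exceed lower")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")

    @property
    def n_segments(self) -> int:
        return int(math.ceil((self.upper - self.lower) / self.spacing - 1e-12))

    @property
    def n_basis(self) -> int:
        return self.n_segments + self.degree

    @property
    def knots(self) -> np.ndarray:
        i = np.arange(-self.degree, self.n_segments + self.degree + 1)
        return self.lower + self.spacing * i


@dataclass(frozen=True)
class PenaltySpec:
    """Difference penalty on adjacent B-spline coefficients."""

    order: int = 2

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("difference order must be >= 1")


def build_basis(spec: BasisSpec, x: np.ndarray) -> sp.csr_matrix:
    """Evaluate the basis at ``x`` -> sparse (len(x), n_basis) matrix.

    Points outside [lower, upper] raise — never silent extrapolation.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x < spec.lower - 1e-9) or np.any(x > spec.upper + 1e-9):
        raise ValueError(
            f"evaluation points outside basis domain [{spec.lower}, {spec.upper}]"
        )
    # clip into the knot span so the right domain endpoint is usable even
    # when ceil() pushed the last knot segment past it
    hi = spec.lower + spec.n_segments * spec.spacing
    xc = np.clip(x, spec.lower, min(spec.upper, hi) - 1e-12 * spec.spacing)
    B = BSpline.design_matrix(xc, spec.knots, spec.degree)
    return sp.csr_matrix(B)


def build_penalty(spec: PenaltySpec, n_basis: int) -> np.ndarray:
    """Penalty matrix D'D for the order-k difference operator D."""
    if spec.order >= n_basis:
        raise ValueError(
            f"difference order {spec.order} must be below basis size {n_basis}"
        )
    D = np.diff(np.eye(n_basis), n=spec.order, axis=0)
    return D.T @ D


@dataclass
class SmoothFit:
    """A fitted P-spline smooth for one stratum (1D slice or 2D surface)."""

    stratum: str
    age_spec: BasisSpec
    coef: np.ndarray  # (Ka,) in 1D; (Ka, Ky) in 2D, log-hazard scale
    lam: float | tuple[float, float]
    deviance: float
    ed: float
    bic: float
    n_obs: int
    converged: bool
    n_iter: int
    years: np.ndarray  # fitted calendar years (length 1 in 1D)
    year_spec: BasisSpec | None = None
    penalty_order: int = 2
    bic_profile: list | None = field(default=None, repr=False)

    @property
    def is_2d(self) -> bool:
        return self.coef.ndim == 2

    # -- text serialization --------------------------------------------
    def to_json(self) -> str:
        d = {
            "stratum": self.stratum,
            "age_spec": vars(self.age_spec).copy(),
            "year_spec": None if self.year_spec is None else vars(self.year_spec).copy(),
            "coef": self.coef.tolist(),
            "lam": self.lam if np.isscalar(self.lam) else list(self.lam),
            "deviance": self.deviance,
            "ed": self.ed,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "years": self.years.tolist(),
            "penalty_order": self.penalty_order,
            "bic_profile": self.bic_profile,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SmoothFit":
        d = json.loads(text)
        return cls(
            stratum=d["stratum"],
            age_spec=BasisSpec(**d["age_spec"]),
            year_spec=None if d["year_spec"] is None else BasisSpec(**d["year_spec"]),
            coef=np.asarray(d["coef"], dtype=float),
            lam=d["lam"] if np.isscalar(d["lam"]) else tuple(d["lam"]),
            deviance=d["deviance"],
            ed=d["ed"],
            bic=d["bic"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            years=np.asarray(d["years"], dtype=int),
            penalty_order=d["penalty_order"],
            bic_profile=d.get("bic_profile"),
        )


class FitError(RuntimeError):
    """Raised when a penalized fit cannot be computed."""


def _poisson_deviance(d: np.ndarray, mu_e: np.ndarray) -> float:
    pos = d > 0
    dev = 2.0 * (np.sum(d[pos] * np.log(d[pos] / mu_e[pos])) - np.sum(d - mu_e))
    return float(dev)


def _irls(
    B: sp.csr_matrix,
    pen: np.ndarray,
    deaths: np.ndarray,
    exposure: np.ndarray,
    theta0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, float, bool, int]:
    """Penalized Poisson IRLS with log-exposure offset.

    Maximizes loglik - (1/2) theta' pen theta.  Returns
    (theta, deviance, ED, converged, n_iter) over cells with E > 0.
    """
    if deaths.sum() <= 0:
        raise FitError("all death counts are zero: log-hazard fit is unbounded below")
    log_e = np.log(exposure)
    p = B.shape[1]
    if theta0 is None:
        # deterministic start: penalized LS of the empirical log rate
        z0 = np.log((deaths + 0.5) / (exposure + 0.5))
        BtB = (B.T @ B).toarray()
        theta = np.linalg.solve(BtB + pen + 1e-8 * np.eye(p), B.T @ z0)
    else:
        theta = theta0.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(B @ theta, -80.0, 20.0)
        mu_e = np.exp(eta + log_e)
        z = eta + (deaths - mu_e) / mu_e
        BW = B.multiply(mu_e[:, None])  # W B
        A = (B.T @ BW).toarray()
        H = A + pen
        try:
            c, low = cho_factor(H + 1e-10 * np.eye(p))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FitError(f"singular penalized Hessian: {exc}") from exc
        theta_new = cho_solve((c, low), np.asarray(BW.T @ z).ravel())
        delta = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        if delta < tol:
            converged = True
            break
    eta = np.clip(B @ theta, -80.0, 20.0)
    mu_e = np.exp(eta + log_e)
    A = (B.T @ B.multiply(mu_e[:, None])).toarray()
    c, low = cho_factor(A + pen + 1e-10 * np.eye(p))
    ed = float(np.trace(cho_solve((c, low), A)))
    dev = _poisson_deviance(deaths, mu_e)
    return theta, dev, ed, converged, it


def fit_1d(
    deaths: np.ndarray,
    exposures: np.ndarray,
    ages: np.ndarray,
    lam: float,
    stratum: str = "",
    year: int = 0,
    age_spec: BasisSpec | None = None,
    penalty: PenaltySpec | None = None,
    theta0: np.ndarray | None = None,
) -> SmoothFit:
    """Smooth one age slice (a single stratum-year) at fixed lambda."""
    deaths = np.asarray(deaths, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    keep = exposures > 0
    if not keep.any():
        raise FitError("no cells with positive exposure")
    penalty = penalty or PenaltySpec()
    age_spec = age_spec or BasisSpec(lower=float(ages.min()), upper=float(ages.max()))
    B = build_basis(age_spec, ages[keep])
    pen = lam * build_penalty(penalty, age_spec.n_basis)
    theta, dev, ed, conv, it = _irls(B, pen, deaths[keep], exposures[keep], theta0)
    n = int(keep.sum())
    return SmoothFit(
        stratum=stratum,
        age_spec=age_spec,
        coef=theta,
        lam=float(lam),
        deviance=dev,
        ed=ed,
        bic=dev + math.log(n) * ed,
        n_obs=n,
        converged=conv,
        n_iter=it,
        years=np.asarray([year], dtype=int),
        penalty_order=penalty.order,
    )


def fit_2d(
    deaths: np.ndarray,
    exposures: np.ndarray,
    ages: np.ndarray,
    years: np.ndarray,
    lam_age: float,
    lam_year: float,
    stratum: str = "",
    age_spec: BasisSpec | None = None,
    year_spec: BasisSpec | None = None,
    penalty: PenaltySpec | None = None,
    theta0: np.ndarray | None = None,
) -> SmoothFit:
    """Smooth a full age x year surface for one stratum at fixed lambdas."""
    deaths = np.asarray(deaths, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    ages = np.asarray(ages, dtype=float)
    years_f = np.asarray(years, dtype=float)
    if lam_age < 0 or lam_year < 0:
        raise ValueError("lambdas must be nonnegative")
    if deaths.shape != (ages.size, years_f.size) or exposures.shape != deaths.shape:
        raise ValueError("deaths/exposures must be (n_ages, n_years) arrays")
    penalty = penalty or PenaltySpec()
    age_spec = age_spec or BasisSpec(lower=float(ages.min()), upper=float(ages.max()))
    year_spec = year_spec or BasisSpec(lower=float(years_f.min()), upper=float(years_f.max()))
    Ba = build_basis(age_spec, ages)
    By = build_basis(year_spec, years_f)
    # row-major cell order (age, year): design = Ba kron By on vec_C(Theta)
    B = sp.kron(Ba, By, format="csr")
    ka, ky = age_spec.n_basis, year_spec.n_basis
    Pa = build_penalty(penalty, ka)
    Py = build_penalty(penalty, ky)
    pen = lam_age * np.kron(Pa, np.eye(ky)) + lam_year * np.kron(np.eye(ka), Py)
    d_flat = deaths.ravel()
    e_flat = exposures.ravel()
    keep = e_flat > 0
    if not keep.any():
        raise FitError("no cells with positive exposure")
    theta, dev, ed, conv, it = _irls(
        B[keep], pen, d_flat[keep], e_flat[keep],
        None if theta0 is None else theta0.ravel(),
    )
    n = int(keep.sum())
    return SmoothFit(
        stratum=stratum,
        age_spec=age_spec,
        year_spec=year_spec,
        coef=theta.reshape(ka, ky),
        lam=(float(lam_age), float(lam_year)),
        deviance=dev,
        ed=ed,
        bic=dev + math.log(n) * ed,
        n_obs=n,
        converged=conv,
        n_iter=it,
        years=np.asarray(years, dtype=int),
        penalty_order=penalty.order,
    )


def select_lambda(
    deaths: np.ndarray,
    exposures: np.ndarray,
    ages: np.ndarray,
    years: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    dim: int = 2,
    stratum: str = "",
    year: int = 0,
    **fit_kwargs,
) -> SmoothFit:
    """Grid-search the smoothing weight(s) by BIC; ties go to smoother fits.

    In 2D the grid is the Cartesian product of ``lambda_grid`` with itself.
    The returned fit records the full BIC profile.  Raises if no grid point
    converges.
    """
    grid = np.unique(np.asarray(lambda_grid if lambda_grid is not None else default_lambda_grid(), dtype=float))
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    best: SmoothFit | None = None
    profile: list = []
    failures: list[str] = []
    theta0 = None
    if dim == 1:
        candidates = [(l,) for l in grid]
    elif dim == 2:
        if years is None:
            raise ValueError("years required for 2D selection")
        candidates = list(itertools.product(grid, grid))
    else:
        raise ValueError("dim must be 1 or 2")
    for lams in candidates:
        try:
            if dim == 1:
                fit = fit_1d(deaths, exposures, ages, lams[0], stratum=stratum,
                             year=year, theta0=theta0, **fit_kwargs)
            else:
                fit = fit_2d(deaths, exposures, ages, years, lams[0], lams[1],
                             stratum=stratum, theta0=theta0, **fit_kwargs)
        except FitError as exc:
            failures.append(f"lambda={lams}: {exc}")
            continue
        theta0 = fit.coef  # warm start along the grid
        entry = {"lam": lams[0] if dim == 1 else list(lams), "bic": fit.bic,
                 "deviance": fit.deviance, "ed": fit.ed, "converged": fit.converged}
        profile.append(entry)
        if not fit.converged:
            failures.append(f"lambda={lams}: no convergence in {fit.n_iter} iterations")
            continue
        # scanning in ascending lambda order with <= breaks ties upward
        if best is None or fit.bic <= best.bic:
            best = fit
    if best is None:
        raise FitError(
            "no lambda on the grid produced a converged fit:\n" + "\n".join(failures)
        )
    best.bic_profile = profile
    return best


def evaluate_hazard(
    fit: SmoothFit,
    year: int,
    step: float = 0.01,
    grid: np.ndarray | None = None,
) -> SmoothHazard:
    """Evaluate a fitted smooth on a fine age grid for one calendar year.

    Years outside the fitted range raise — the smoother never extrapolates.
    """
    if year not in fit.years:
        raise ValueError(f"year {year} outside fitted range {fit.years.min()}-{fit.years.max()}")
    if grid is None:
        lo, hi = fit.age_spec.lower, fit.age_spec.upper
        n = int(round((hi - lo) / step)) + 1
        grid = np.linspace(lo, hi, n)
    Ba = build_basis(fit.age_spec, grid)
    if fit.is_2d:
        assert fit.year_spec is not None
        by = build_basis(fit.year_spec, np.asarray([float(year)])).toarray().ravel()
        coef_age = fit.coef @ by
    else:
        coef_age = fit.coef
    log_mu = np.asarray(Ba @ coef_age).ravel()
    return survival_and_density(grid, np.exp(log_mu), stratum=fit.stratum, year=int(year))
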