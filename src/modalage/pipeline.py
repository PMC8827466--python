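"""End-to-end analysis: data -> per-stratum smoothing -> indicator trends.

Also houses the two robustness analyses: sensitivity of the modal age to
left truncation of the age range, and the comparison of modal-age trends
from two-dimensional (age x year) smoothing versus year-by-year
one-dimensional smoothing.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import MortalityDataset, read_dataset, write_dataset
from .indicators import DEFAULT_MODE_FLOOR, compute_indicators, indicator_trends
from .psplines import (
    BasisSpec,
    FitError,
    PenaltySpec,
    SmoothFit,
    default_lambda_grid,
    evaluate_hazard,
    select_lambda,
)
from . import synthetic

logger = logging.getLogger("modalage")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_full",
    "fit_all_strata",
    "truncation_sensitivity",
    "compare_1d_2d",
]


@dataclass
class PipelineConfig:
    """Everything a run needs; maps one-to-one onto CLI flags and YAML."""

    input_path: str | None = None          # long-format dataset to ingest ...
    scenario: str | None = "finnish_like"  # ... or a built-in scenario name
    strata: list[str] | None = None        # subset of stratum labels, or all
    # smoothing
    knot_spacing: float = 5.0
    degree: int = 3
    penalty_order: int = 2
    log10_lambdas: list[float] = field(default_factory=lambda: list(range(-2, 7)))
    smoother: str = "2d"                   # "2d" or "1d"
    # indicators
    grid_step: float = 0.01
    mode_floor: float = DEFAULT_MODE_FLOOR
    thresholds: tuple[float, float] = (65.0, 75.0)
    quantile_p: float = 0.80
    reference_class: str = "upper_nonmanual"
    # sensitivity
    truncation_ages: tuple[int, ...] = (31, 35, 40)
    # run control
    outdir: str | None = None
    seed: int = 0
    n_years: int = 45
    exposure: float = 2e4
    verbosity: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not (lo < hi):
            raise ValueError("thresholds must be increasing")
        if any(a >= self.mode_floor for a in self.truncation_ages):
            raise ValueError("all truncation start ages must lie below the mode floor")
        if self.smoother not in ("1d", "2d"):
            raise ValueError("smoother must be '1d' or '2d'")

    @property
    def lambda_grid(self) -> np.ndarray:
        return 10.0 ** np.asarray(self.log10_lambdas, dtype=float)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        if "truncation_ages" in raw:
            raw["truncation_ages"] = tuple(raw["truncation_ages"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["truncation_ages"] = list(self.truncation_ages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class PipelineResult:
    dataset: MortalityDataset
    fits: dict[str, SmoothFit]
    table: pd.DataFrame


def load_or_simulate(config: PipelineConfig) -> MortalityDataset:
    if config.input_path is not None:
        ds = read_dataset(config.input_path)
    elif config.scenario == "finnish_like":
        ds = synthetic.finnish_like_scenario(
            seed=config.seed, n_years=config.n_years, exposure=config.exposure
        )
    else:
        raise ValueError(f"unknown scenario {config.scenario!r} and no input path")
    if config.strata:
        keep = [i for i, s in enumerate(ds.strata) if s.label in set(config.strata)]
        if not keep:
            raise ValueError("no requested strata present in the data")
        ds = MortalityDataset(
            ages=ds.ages,
            years=ds.years,
            strata=[ds.strata[i] for i in keep],
            deaths=ds.deaths[keep],
            exposures=ds.exposures[keep],
            true_hazard=None if ds.true_hazard is None else ds.true_hazard[keep],
            meta=ds.meta,
        )
    return ds


def _specs(config: PipelineConfig, ds: MortalityDataset):
    age_spec = BasisSpec(
        lower=float(ds.ages.min()), upper=float(ds.ages.max()),
        spacing=config.knot_spacing, degree=config.degree,
    )
    year_spec = BasisSpec(
        lower=float(ds.years.min()), upper=float(ds.years.max()),
        spacing=config.knot_spacing, degree=config.degree,
    )
    return age_spec, year_spec, PenaltySpec(order=config.penalty_order)


def fit_all_strata(ds: MortalityDataset, config: PipelineConfig) -> dict[str, SmoothFit]:
    """BIC-selected 2D fit per stratum, each with its own smoothing weights."""
    age_spec, year_spec, pen = _specs(config, ds)
    fits: dict[str, SmoothFit] = {}
    for s in ds.strata:
        deaths, expos = ds.slice(s)
        t0 = time.perf_counter()
        try:
            fit = select_lambda(
                deaths, expos, ds.ages, ds.years,
                lambda_grid=config.lambda_grid, dim=2, stratum=s.label,
                age_spec=age_spec, year_spec=year_spec, penalty=pen,
            )
        except FitError as exc:
            raise FitError(f"stratum {s.label}: {exc}") from exc
        logger.info(
            "fitted %s: lambda=%s BIC=%.1f ED=%.1f (%.2fs, %d iter, converged=%s)",
            s.label, fit.lam, fit.bic, fit.ed,
            time.perf_counter() - t0, fit.n_iter, fit.converged,
        )
        fits[s.label] = fit
    return fits


def run_full(config: PipelineConfig) -> PipelineResult:
    """Simulate or ingest, smooth every stratum, tabulate indicator trends.

    Deterministic given config and seed.  When ``outdir`` is set, writes
    the dataset, per-stratum fit archives, the indicator table and a log.
    """
    _setup_logging(config)
    ds = load_or_simulate(config)
    fits = fit_all_strata(ds, config)
    table = indicator_trends(
        fits.values(),
        reference_class=config.reference_class,
        grid_step=config.grid_step,
        mode_floor=config.mode_floor,
        thresholds=config.thresholds,
        quantile_p=config.quantile_p,
    )
    for _, row in table.iterrows():
        logger.info(
            "%s %d: M=%.2f%s e65=%.2f p(M)=%.3f",
            row["stratum"], row["year"], row["M"],
            " [boundary]" if row["mode_flagged"] else "",
            row["e65"], row["p_surv_M"],
        )
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(ds, str(out / "dataset.csv"))
        (out / "fits").mkdir(exist_ok=True)
        for label, fit in fits.items():
            (out / "fits" / f"{label.replace(':', '_')}.json").write_text(fit.to_json())
        table.to_csv(out / "indicators.tsv", sep="\t", index=False)
        config.to_yaml(str(out / "config.yaml"))
    return PipelineResult(dataset=ds, fits=fits, table=table)


def truncation_sensitivity(
    ds: MortalityDataset, config: PipelineConfig, tolerance: float = 0.1
) -> pd.DataFrame:
    """Refit with the age range left-truncated at each start age; compare M.

    Returns one row per stratum-year with the modal age under every start
    age, the largest absolute difference versus the first start age, and a
    pass flag at ``tolerance`` years.
    """
    starts = list(config.truncation_ages)
    if any(a >= config.mode_floor for a in starts):
        raise ValueError("truncation start ages must lie below the mode floor")
    m_tables = {}
    for start in starts:
        key = f"M_start{start}"
        if key in m_tables:  # duplicated start age: reuse
            continue
        sub = ds.truncate_below(start)
        fits = fit_all_strata(sub, config)
        tab = indicator_trends(
            fits.values(), reference_class=None, grid_step=config.grid_step,
            mode_floor=config.mode_floor, thresholds=config.thresholds,
            quantile_p=config.quantile_p,
        )
        m_tables[key] = tab.set_index(["stratum", "year"])["M"]
    result = pd.DataFrame({f"M_start{s}": m_tables[f"M_start{s}"] for s in starts})
    base = result[f"M_start{starts[0]}"]
    result["max_abs_dM"] = result.sub(base, axis=0).abs().max(axis=1)
    result["within_tolerance"] = result["max_abs_dM"] <= tolerance
    return result.reset_index()


def compare_1d_2d(ds: MortalityDataset, config: PipelineConfig) -> pd.DataFrame:
    """Modal-age trends from 2D smoothing vs year-by-year 1D smoothing.

    Roughness of each M series is the mean squared second difference;
    year-over-year fluctuation that 2D smoothing borrows strength across
    years to suppress.  A year whose 1D fit fails is recorded as missing
    and skipped in the roughness (computed over complete triplets only).
    """
    if ds.years.size < 10:
        raise ValueError("need at least 10 years of data to compare smoothers")
    age_spec, _, pen = _specs(config, ds)
    fits2d = fit_all_strata(ds, config)
    records = []
    for s in ds.strata:
        deaths, expos = ds.slice(s)
        m2d, m1d = [], []
        for j, year in enumerate(ds.years):
            sh = evaluate_hazard(fits2d[s.label], int(year), step=config.grid_step)
            m2d.append(compute_indicators(sh, mode_floor=config.mode_floor).M)
            try:
                fit1 = select_lambda(
                    deaths[:, j], expos[:, j], ds.ages,
                    lambda_grid=config.lambda_grid, dim=1, stratum=s.label,
                    year=int(year), age_spec=age_spec, penalty=pen,
                )
                sh1 = evaluate_hazard(fit1, int(year), step=config.grid_step)
                m1d.append(compute_indicators(sh1, mode_floor=config.mode_floor).M)
            except FitError:
                logger.warning("1D fit failed for %s %d; marked missing", s.label, year)
                m1d.append(np.nan)
        records.append(
            {
                "stratum": s.label,
                "M_2d": np.asarray(m2d),
                "M_1d": np.asarray(m1d),
                "roughness_2d": _roughness(np.asarray(m2d)),
                "roughness_1d": _roughness(np.asarray(m1d)),
            }
        )
    out = pd.DataFrame(records)
    out["roughness_ratio"] = out["roughness_2d"] / out["roughness_1d"]
    return out


def _roughness(series: np.ndarray) -> float:
    """Mean squared second difference over complete consecutive triplets."""
    d2 = series[2:] - 2.0 * series[1:-1] + series[:-2]
    d2 = d2[np.isfinite(d2)]
    if d2.size == 0:
        return float("nan")
    return float(np.mean(d2**2))


def _setup_logging(config: PipelineConfig) -> None:
    level = logging.WARNING if config.verbosity == 0 else logging.INFO
    logger.setLevel(level)
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
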