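"""Stratified Lexis surfaces of death counts and person-years of exposure.

A :class:`MortalityDataset` holds, for each stratum (sex x occupational
class, or any user-defined grouping), rectangular age x calendar-year
arrays of observed death counts and exposures.  Ages and years are single
consecutive years.  Synthetic datasets additionally carry the true hazard
surface they were sampled from, which downstream tests use as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = ["Stratum", "MortalityDataset", "write_dataset", "read_dataset"]


@dataclass(frozen=True, order=True)
class Stratum:
    """One population stratum, conventionally sex x occupational class."""

    sex: str
    klass: str

    @property
    def label(self) -> str:
        return f"{self.sex}:{self.klass}"

    @classmethod
    def from_label(cls, label: str) -> "Stratum":
        sex, _, klass = label.partition(":")
        return cls(sex=sex, klass=klass)


@dataclass
class MortalityDataset:
    """Death counts and exposures on a common age x year grid per stratum.

    Parameters
    ----------
    ages, years
        Consecutive integer vectors shared by all strata.
    strata
        Ordered stratum labels.
    deaths, exposures
        Arrays of shape ``(n_strata, n_ages, n_years)``; deaths are
        nonnegative counts, exposures nonnegative person-years.
    true_hazard
        Optional ground-truth hazard surface of the same shape (synthetic
        data only).
    meta
        Free-form provenance (scenario parameters, seed, source file).
    """

    ages: np.ndarray
    years: np.ndarray
    strata: list[Stratum]
    deaths: np.ndarray
    exposures: np.ndarray
    true_hazard: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.exposures = np.asarray(self.exposures, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        shape = (len(self.strata), self.ages.size, self.years.size)
        if self.deaths.shape != shape or self.exposures.shape != shape:
            raise ValueError(
                f"deaths/exposures must have shape {shape}, got "
                f"{self.deaths.shape} and {self.exposures.shape}"
            )
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be consecutive single years")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive calendar years")
        if np.any(self.deaths < 0):
            raise ValueError("negative death counts")
        if np.any(self.exposures < 0):
            raise ValueError("negative exposures")
        if np.any((self.exposures == 0) & (self.deaths > 0)):
            raise ValueError("deaths observed in cells with zero exposure")
        if self.true_hazard is not None and self.true_hazard.shape != shape:
            raise ValueError("true_hazard shape mismatch")

    # -- access helpers -------------------------------------------------
    def index_of(self, stratum: Stratum | str) -> int:
        if isinstance(stratum, str):
            stratum = Stratum.from_label(stratum)
        return self.strata.index(stratum)

    def slice(self, stratum: Stratum | str) -> tuple[np.ndarray, np.ndarray]:
        """Return (deaths, exposures) age x year arrays for one stratum."""
        i = self.index_of(stratum)
        return self.deaths[i], self.exposures[i]

    def truncate_below(self, start_age: int) -> "MortalityDataset":
        """Left-truncate the age range at ``start_age`` (inclusive)."""
        keep = self.ages >= start_age
        if keep.sum() < 10:
            raise ValueError(f"fewer than 10 ages remain above {start_age}")
        return MortalityDataset(
            ages=self.ages[keep],
            years=self.years,
            strata=list(self.strata),
            deaths=self.deaths[:, keep, :],
            exposures=self.exposures[:, keep, :],
            true_hazard=None if self.true_hazard is None else self.true_hazard[:, keep, :],
            meta={**self.meta, "truncated_at": int(start_age)},
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: stratum, sex, class, age, year, deaths, exposure."""
        rows = []
        for i, s in enumerate(self.strata):
            age_grid, year_grid = np.meshgrid(self.ages, self.years, indexing="ij")
            rows.append(
                pd.DataFrame(
                    {
                        "stratum": s.label,
                        "sex": s.sex,
                        "class": s.klass,
                        "age": age_grid.ravel(),
                        "year": year_grid.ravel(),
                        "deaths": self.deaths[i].ravel(),
                        "exposure": self.exposures[i].ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def write_dataset(ds: MortalityDataset, path: str) -> None:
    """Write a dataset as long-format delimited text plus a YAML sidecar.

    The sidecar (``<path>.meta.yaml``) records provenance: scenario
    parameters and seed for synthetic data, or whatever ``ds.meta`` holds.
    """
    ds.to_frame().to_csv(path, index=False)
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(ds.meta, fh, sort_keys=True)


def read_dataset(path: str) -> MortalityDataset:
    """Read a long-format dataset written by :func:`write_dataset`.

    Also the ingestion path for user-supplied data (e.g. HMD death and
    exposure tables reshaped to the documented columns).
    """
    df = pd.read_csv(path)
    required = {"stratum", "age", "year", "deaths", "exposure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    ages = np.sort(df["age"].unique())
    years = np.sort(df["year"].unique())
    labels = sorted(df["stratum"].unique())
    strata = [Stratum.from_label(l) for l in labels]
    deaths = np.zeros((len(strata), ages.size, years.size))
    expos = np.zeros_like(deaths)
    a_idx = {a: i for i, a in enumerate(ages)}
    y_idx = {y: i for i, y in enumerate(years)}
    for k, label in enumerate(labels):
        sub = df[df["stratum"] == label]
        if len(sub) != ages.size * years.size:
            raise ValueError(f"stratum {label!r} is not a full age x year grid")
        ii = sub["age"].map(a_idx).to_numpy()
        jj = sub["year"].map(y_idx).to_numpy()
        deaths[k, ii, jj] = sub["deaths"].to_numpy()
        expos[k, ii, jj] = sub["exposure"].to_numpy()
    meta: dict = {}
    try:
        with open(f"{path}.meta.yaml") as fh:
            meta = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        pass
    return MortalityDataset(
        ages=ages, years=years, strata=strata, deaths=deaths, exposures=expos, meta=meta
    )
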