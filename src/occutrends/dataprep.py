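"""Turn raw specimen/observation records into model-ready detection histories.

Historical record tables (one row per specimen) are collapsed to annual
presence/absence per species and region.  A region-year counts as *surveyed*
when at least one record of the focal taxon exists there; in surveyed years a
species is present (1) if it has a record and absent (0) otherwise, and in
unsurveyed years its state is missing.  Recording effort is the total record
count of the taxon in that region-year and later drives detection probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DetectionData",
    "CovariateSeries",
    "Standardizer",
    "load_records",
    "load_covariates",
    "load_traits",
    "build_detection_data",
    "filter_species",
    "standardize_covariates",
]

MISSING = -1  # sentinel for unsurveyed cells in the int8 detection tensor


@dataclass
class DetectionData:
    """Binary detection histories for one taxon.

    Attributes
    ----------
    y : int8 array, shape (S, R, T)
        1 detected, 0 surveyed-but-undetected, -1 missing (unsurveyed).
    surveyed : bool array, shape (R, T)
        True where the taxon has >=1 record in that region-year.
    effort : int array, shape (R, T)
        Total taxon record count per region-year.
    years : int array, shape (T,)
    species : list of str
    regions : list
    """

    y: np.ndarray
    surveyed: np.ndarray
    effort: np.ndarray
    years: np.ndarray
    species: list
    regions: list

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.surveyed = np.asarray(self.surveyed, dtype=bool)
        self.effort = np.asarray(self.effort)
        self.years = np.asarray(self.years)
        S, R, T = self.y.shape
        if self.surveyed.shape != (R, T) or self.effort.shape != (R, T):
            raise ValueError("surveyed/effort axes inconsistent with y")
        if len(self.species) != S or len(self.regions) != R or len(self.years) != T:
            raise ValueError("axis labels inconsistent with y")
        if np.any(self.effort < 0):
            raise ValueError("effort must be nonnegative")
        if np.any((self.effort == 0) & self.surveyed):
            raise ValueError("surveyed region-years must have effort > 0")
        if np.any((self.y == MISSING) != ~self.surveyed[None, :, :]):
            raise ValueError("y must be missing exactly where unsurveyed")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_regions(self) -> int:
        return self.y.shape[1]

    @property
    def n_years(self) -> int:
        return self.y.shape[2]

    def species_slice(self, name: str) -> np.ndarray:
        return self.y[self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy serialization: one row per (species, region, year)."""
        S, R, T = self.y.shape
        sp = np.repeat(self.species, R * T)
        rg = np.tile(np.repeat(self.regions, T), S)
        yr = np.tile(self.years, S * R)
        return pd.DataFrame(
            {
                "species": sp,
                "region": rg,
                "year": yr,
                "detected": self.y.ravel(),
                "surveyed": np.tile(self.surveyed.astype(int).ravel(), S),
                "effort": np.tile(self.effort.ravel(), S),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DetectionData":
        species = list(pd.unique(df["species"]))
        regions = sorted(pd.unique(df["region"]))
        years = np.sort(pd.unique(df["year"]))
        S, R, T = len(species), len(regions), len(years)
        si = pd.Categorical(df["species"], categories=species).codes
        ri = pd.Categorical(df["region"], categories=regions).codes
        ti = np.searchsorted(years, df["year"].to_numpy())
        y = np.full((S, R, T), MISSING, dtype=np.int8)
        y[si, ri, ti] = df["detected"].to_numpy()
        surveyed = np.zeros((R, T), dtype=bool)
        surveyed[ri, ti] = df["surveyed"].to_numpy().astype(bool)
        effort = np.zeros((R, T), dtype=int)
        effort[ri, ti] = df["effort"].to_numpy()
        return cls(y, surveyed, effort, years, species, regions)


@dataclass
class CovariateSeries:
    """Annual environmental covariates per region, complete over the span."""

    temperature: np.ndarray  # (R, T)
    forest_cover: np.ndarray  # (R, T), fraction in [0, 1]
    years: np.ndarray  # (T,)
    regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.forest_cover = np.asarray(self.forest_cover, dtype=float)
        self.years = np.asarray(self.years)
        if self.temperature.shape != self.forest_cover.shape:
            raise ValueError("temperature and forest_cover shapes differ")
        if not np.all(np.isfinite(self.temperature)) or not np.all(
            np.isfinite(self.forest_cover)
        ):
            raise ValueError("covariate series must be complete (no gaps)")
        if np.any((self.forest_cover < 0) | (self.forest_cover > 1)):
            raise ValueError("forest_cover must lie in [0, 1]")

    @property
    def year_linear(self) -> np.ndarray:
        """Centered/scaled year axis (population z-score)."""
        yr = self.years.astype(float)
        return (yr - yr.mean()) / yr.std()

    def subset_years(self, years: np.ndarray) -> "CovariateSeries":
        idx = np.searchsorted(self.years, years)
        if not np.array_equal(self.years[idx], years):
            raise ValueError("requested years missing from covariate series")
        return CovariateSeries(
            self.temperature[:, idx], self.forest_cover[:, idx], years, self.regions
        )


class Standardizer:
    """Reversible z-scoring (population SD); effort goes through log1p first."""

    def __init__(self, x: np.ndarray, log1p: bool = False, name: str = "covariate"):
        x = np.asarray(x, dtype=float)
        self.log1p = log1p
        self.name = name
        t = np.log1p(x) if log1p else x
        self.mean = float(t.mean())
        self.sd = float(t.std())
        if self.sd == 0.0:
            raise ValueError(f"zero-variance covariate: {name}")

    def transform(self, x: np.ndarray) -> np.ndarray:
        t = np.log1p(np.asarray(x, dtype=float)) if self.log1p else np.asarray(x, float)
        return (t - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        t = np.asarray(z, float) * self.sd + self.mean
        return np.expm1(t) if self.log1p else t


def load_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "region", "year", "taxon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records file {path} missing columns: {sorted(missing)}")
    if df[list(required)].isna().any().any():
        raise ValueError(f"records file {path} has missing fields")
    return df


def load_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"region", "year", "temperature", "forest_cover"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate file {path} missing columns: {sorted(missing)}")
    return df


def covariates_from_frame(df: pd.DataFrame) -> CovariateSeries:
    regions = sorted(df["region"].unique())
    years = np.sort(df["year"].unique())
    temp = (
        df.pivot(index="region", columns="year", values="temperature")
        .loc[regions, years]
        .to_numpy()
    )
    forest = (
        df.pivot(index="region", columns="year", values="forest_cover")
        .loc[regions, years]
        .to_numpy()
    )
    return CovariateSeries(temp, forest, years, regions)


def load_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "endemism"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait file {path} missing columns: {sorted(missing)}")
    for col in ("habitat", "host_plant"):
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].fillna("unknown")
    if df["endemism"].isna().any():
        raise ValueError("every species needs an endemism entry")
    return df.set_index("species")


def build_detection_data(
    records: pd.DataFrame,
    taxon: str,
    regions=None,
    span: tuple[int, int] | None = None,
    species: list[str] | None = None,
) -> DetectionData:
    """Collapse record rows to annual detection histories for one taxon.

    ``species`` optionally restricts the species axis (study species) while
    effort still counts every record of the taxon, including records of
    species outside the study list.
    """
    sub = records[records["taxon"] == taxon]
    if sub.empty:
        raise ValueError(f"no records for taxon {taxon!r}")
    if regions is None:
        regions = sorted(sub["region"].unique())
    regions = list(regions)
    if span is None:
        span = (int(sub["year"].min()), int(sub["year"].max()))
    lo, hi = span
    bad = sub[(sub["year"] < lo) | (sub["year"] > hi)]
    if not bad.empty:
        offenders = bad[["species", "region", "year"]].head(10).to_dict("records")
        raise ValueError(f"records outside span {span}: {offenders}")
    bad_region = sub[~sub["region"].isin(regions)]
    if not bad_region.empty:
        raise ValueError(
            f"records outside region set: {sorted(bad_region['region'].unique())}"
        )

    years = np.arange(lo, hi + 1)
    if species is None:
        species = sorted(sub["species"].unique())
    species = list(species)
    S, R, T = len(species), len(regions), len(years)

    ri = pd.Categorical(sub["region"], categories=regions).codes
    ti = sub["year"].to_numpy() - lo
    effort = np.zeros((R, T), dtype=int)
    np.add.at(effort, (ri, ti), 1)
    surveyed = effort > 0

    y = np.broadcast_to(
        np.where(surveyed, 0, MISSING).astype(np.int8), (S, R, T)
    ).copy()
    insp = sub["species"].isin(species)
    si = pd.Categorical(sub.loc[insp, "species"], categories=species).codes
    y[si, ri[insp.to_numpy()], ti[insp.to_numpy()]] = 1
    return DetectionData(y, surveyed, effort, years, species, regions)


def filter_species(data: DetectionData, min_years: int = 2) -> DetectionData:
    """Keep species detected in at least ``min_years`` distinct years."""
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    detected_any_region = (data.y == 1).any(axis=1)  # (S, T)
    n_years = detected_any_region.sum(axis=1)
    keep = n_years >= min_years
    if not keep.any():
        raise ValueError("all species removed by the detection-year filter")
    return DetectionData(
        data.y[keep],
        data.surveyed,
        data.effort,
        data.years,
        [s for s, k in zip(data.species, keep) if k],
        data.regions,
    )


def standardize_covariates(
    cov: CovariateSeries, effort: np.ndarray
) -> dict[str, Standardizer]:
    """Fit reversible standardizers for every design input.

    Effort is log1p-transformed before z-scoring (record counts are heavy
    tailed); year uses the covariate series' year axis.
    """
    return {
        "temperature": Standardizer(cov.temperature, name="temperature"),
        "forest": Standardizer(cov.forest_cover, name="forest"),
        "effort": Standardizer(np.asarray(effort), log1p=True, name="effort"),
        "year": Standardizer(cov.years.astype(float), name="year"),
    }
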