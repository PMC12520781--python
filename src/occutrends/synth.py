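"""Synthetic museum-record studies from a known dynamic occupancy process.

Emulates the structure of multi-region historical collection data: a long
annual span, a handful of regions, strongly uneven zero-inflated recording
effort with occasional expedition bursts, covariate-driven colonization and
extinction, and effort-driven detection.  The generator records full latent
truth (occupancy states and analytic marginal probabilities) so downstream
estimators can be scored against it.

Default scales mirror a museum-collection study: 3 regions, a 170-year span,
~20 modelled species, a few records per region-year with most region-years
unsurveyed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ._hmm import project_occupancy, simulate_detections, simulate_states
from .dataprep import CovariateSeries, DetectionData, Standardizer

__all__ = ["SpeciesParams", "SimConfig", "SimTruth", "generate_covariates",
           "simulate_detection_history", "generate_study"]


@dataclass
class SpeciesParams:
    """True logit-scale parameters for one species.

    ``dynamics`` names the covariate driving gamma/eps ("constant", "year",
    "temperature" or "forest"); slopes are ignored for "constant".
    """

    name: str
    psi1: float = 1.0
    gamma_intercept: float = -1.5
    gamma_slope: float = 0.0
    eps_intercept: float = -1.5
    eps_slope: float = 0.0
    p_intercept: float = -0.5
    p_effort: float = 1.0
    dynamics: str = "constant"
    endemism: str = "endemic"
    habitat: str = "unknown"
    host_plant: str = "unknown"


@dataclass
class SimConfig:
    n_species: int = 20
    n_regions: int = 3
    start_year: int = 1853
    n_years: int = 170
    taxon: str = "TaxonA"
    # temperature: linear trend + Gaussian noise, per region
    temp_intercept: float = 26.0
    temp_trend: float = 0.006  # degrees C / year
    temp_noise_sd: float = 0.25
    temp_region_offset: float = 0.5  # deterministic offset between regions
    # forest cover: monotone logistic decline
    forest_start: float = 0.95
    forest_end: float = 0.35
    forest_midpoint: float = 110.0  # years after start_year
    forest_rate: float = 0.06  # per-year logistic rate; 0 -> constant
    # effort regime: zero-inflated negative binomial with expedition bursts
    effort_mean: float = 3.0  # expected records per surveyed region-year
    zero_inflation: float = 0.55  # probability of a structural zero
    nb_dispersion: float = 1.0  # NB size; smaller = burstier
    expedition_prob: float = 0.03
    expedition_scale: float = 8.0  # effort multiplier in expedition years
    # species hyper-ranges (logit scale) used when species_params not given
    psi1: float = 1.0
    gamma_intercept_range: tuple = (-2.5, -0.5)
    eps_intercept_range: tuple = (-2.5, -0.5)
    dyn_slope_range: tuple = (0.0, 0.0)
    p_intercept_range: tuple = (-1.0, 0.5)
    p_effort_slope: float = 1.0
    dynamics: str = "constant"
    # additive logit-year trend shifts by trait class (gamma_shift, eps_shift)
    trait_trend_shifts: dict = field(default_factory=dict)
    # trait assignment probabilities
    p_endemic: float = 0.5
    p_forest_dependent: float = 0.5
    p_specialist: float = 0.5
    p_trait_known: float = 1.0  # habitat/host known with this probability
    species_params: list | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("zero_inflation", "expedition_prob", "forest_start",
                     "forest_end", "psi1", "p_endemic", "p_forest_dependent",
                     "p_specialist", "p_trait_known"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_years < 2:
            raise ValueError("span must cover at least 2 years")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    @property
    def regions(self) -> list:
        return list(range(1, self.n_regions + 1))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["species_params"] is not None:
            d["species_params"] = [dataclasses.asdict(s) if not isinstance(s, dict)
                                   else s for s in self.species_params]
        return json.dumps(d, indent=2, default=list)


@dataclass
class SimTruth:
    """Latent truth of a simulated study."""

    z: np.ndarray  # (S, R, T) latent occupancy states
    marginal_prob: np.ndarray  # (S, R, T) analytic Pr(z=1)
    expected_richness: np.ndarray  # (R, T) = sum_s marginal_prob
    species_params: list
    years: np.ndarray
    regions: list
    seed: int
    detection_prob: np.ndarray | None = None  # (S, R, T) true p used to draw y


def generate_covariates(config: SimConfig) -> CovariateSeries:
    """Linear-trend temperature with noise; logistic forest-cover decline."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    t = np.arange(config.n_years, dtype=float)
    R = config.n_regions
    offs = config.temp_region_offset * np.arange(R)[:, None]
    temp = (config.temp_intercept + offs + config.temp_trend * t[None, :]
            + rng.normal(0.0, config.temp_noise_sd, size=(R, config.n_years)))
    forest = config.forest_end + (config.forest_start - config.forest_end) * expit(
        -(t - config.forest_midpoint) * config.forest_rate
    )
    forest = np.clip(np.broadcast_to(forest, (R, config.n_years)).copy(), 0.0, 1.0)
    return CovariateSeries(temp, forest, config.years, config.regions)


def _draw_species_params(config: SimConfig, rng) -> list[SpeciesParams]:
    width = max(2, len(str(config.n_species)))
    out = []
    for i in range(config.n_species):
        endemism = "endemic" if rng.random() < config.p_endemic else "non-endemic"
        if rng.random() < config.p_trait_known:
            habitat = ("forest-dependent" if rng.random() < config.p_forest_dependent
                       else "open-habitat tolerant")
            host = ("specialist" if rng.random() < config.p_specialist
                    else "generalist")
        else:
            habitat = host = "unknown"
        gs = rng.uniform(*config.dyn_slope_range)
        es = rng.uniform(*config.dyn_slope_range)
        dgs, des = config.trait_trend_shifts.get(endemism, (0.0, 0.0))
        out.append(SpeciesParams(
            name=f"sp_{i:0{width}d}",
            psi1=config.psi1,
            gamma_intercept=rng.uniform(*config.gamma_intercept_range),
            gamma_slope=gs + dgs,
            eps_intercept=rng.uniform(*config.eps_intercept_range),
            eps_slope=es + des,
            p_intercept=rng.uniform(*config.p_intercept_range),
            p_effort=config.p_effort_slope,
            dynamics=config.dynamics,
            endemism=endemism,
            habitat=habitat,
            host_plant=host,
        ))
    return out


def _dynamics_covariate(sp: SpeciesParams, cov: CovariateSeries, R: int):
    if sp.dynamics == "constant":
        return np.zeros((R, len(cov.years)))
    if sp.dynamics == "year":
        return np.broadcast_to(cov.year_linear, (R, len(cov.years)))
    if sp.dynamics == "temperature":
        x = cov.temperature
        return (x - x.mean()) / x.std()
    if sp.dynamics == "forest":
        x = cov.forest_cover
        return (x - x.mean()) / x.std()
    raise ValueError(f"unknown dynamics covariate {sp.dynamics!r}")


def simulate_detection_history(
    config: SimConfig, cov: CovariateSeries | None = None
) -> tuple[DetectionData, SimTruth]:
    """Run the occupancy process forward and observe it through uneven effort.

    Detection uses the same effort transform the fitting side applies
    (z-scored log1p record counts), so true detection coefficients live in
    the estimated parameterization.
    """
    if cov is None:
        cov = generate_covariates(config)
    ss = np.random.SeedSequence([config.seed, 2])
    rng_effort, rng_params, *rng_species = [
        np.random.default_rng(s) for s in ss.spawn(2 + config.n_species)
    ]
    R, T = config.n_regions, config.n_years

    # effort: zero-inflated negative binomial with expedition bursts
    structural_zero = rng_effort.random((R, T)) < config.zero_inflation
    burst = rng_effort.random((R, T)) < config.expedition_prob
    mu = np.where(burst, config.effort_mean * config.expedition_scale,
                  config.effort_mean)
    k = config.nb_dispersion
    counts = rng_effort.negative_binomial(k, k / (k + mu))
    effort = np.where(structural_zero, 0, counts).astype(int)
    surveyed = effort > 0
    eff_std = Standardizer(effort, log1p=True, name="effort").transform(effort)

    sp_params = (list(config.species_params) if config.species_params is not None
                 else _draw_species_params(config, rng_params))
    if len(sp_params) != config.n_species:
        raise ValueError("species_params length differs from n_species")

    S = config.n_species
    z = np.empty((S, R, T), dtype=np.int8)
    y = np.empty((S, R, T), dtype=np.int8)
    marg = np.empty((S, R, T))
    true_p = np.empty((S, R, T))
    for s, sp in enumerate(sp_params):
        x = _dynamics_covariate(sp, cov, R)
        gamma = expit(sp.gamma_intercept + sp.gamma_slope * x)
        eps = expit(sp.eps_intercept + sp.eps_slope * x)
        p = expit(sp.p_intercept + sp.p_effort * eff_std)
        rng_s = rng_species[s]
        z[s] = simulate_states(rng_s, sp.psi1, gamma, eps)
        y[s] = simulate_detections(rng_s, z[s], p, surveyed)
        marg[s] = project_occupancy(sp.psi1, gamma, eps)
        true_p[s] = p

    # a record table implies at least one record per detected species, so
    # raise the record count where simultaneous detections exceed it
    # (detection itself was generated from the pre-adjustment counts)
    n_det = (y == 1).sum(axis=0)
    effort = np.maximum(effort, n_det)

    data = DetectionData(y, surveyed, effort, config.years,
                         [sp.name for sp in sp_params], config.regions)
    truth = SimTruth(z=z, marginal_prob=marg,
                     expected_richness=marg.sum(axis=0),
                     species_params=sp_params, years=config.years,
                     regions=config.regions, seed=config.seed,
                     detection_prob=true_p)
    return data, truth


def records_from_detections(data: DetectionData, taxon: str,
                            indet_name: str | None = None) -> pd.DataFrame:
    """Expand a detection tensor back into one-row-per-specimen records.

    Every detected species gets one record; remaining effort in a region-year
    is spread evenly over the detected species.  Region-years whose records
    all belong to species outside the study list are written under an
    indeterminate background name, so effort round-trips exactly.
    """
    if indet_name is None:
        indet_name = f"{taxon}_indet"
    rows = []
    S, R, T = data.y.shape
    for r in range(R):
        for t in range(T):
            e = int(data.effort[r, t])
            if e == 0:
                continue
            det = [data.species[s] for s in range(S) if data.y[s, r, t] == 1]
            year = int(data.years[t])
            region = data.regions[r]
            if not det:
                rows += [(indet_name, region, year, taxon)] * e
                continue
            base, extra = divmod(max(e - len(det), 0), len(det))
            for i, name in enumerate(det):
                n = 1 + base + (1 if i < extra else 0)
                rows += [(name, region, year, taxon)] * n
    return pd.DataFrame(rows, columns=["species", "region", "year", "taxon"])


def generate_study(config: SimConfig, out_dir) -> dict:
    """Write the full CSV bundle one run of the pipeline consumes.

    Returns a dict of paths: records, covariates, traits, truth_richness,
    truth_states, config — everything needed to score estimates against truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov = generate_covariates(config)
    data, truth = simulate_detection_history(config, cov)

    paths = {k: out / f"{k}.csv" for k in
             ("records", "covariates", "traits", "truth_richness", "truth_states")}
    paths["config"] = out / "sim_config.json"
    try:
        records_from_detections(data, config.taxon).to_csv(
            paths["records"], index=False)
        R, T = config.n_regions, config.n_years
        pd.DataFrame({
            "region": np.repeat(config.regions, T),
            "year": np.tile(config.years, R),
            "temperature": cov.temperature.ravel(),
            "forest_cover": cov.forest_cover.ravel(),
        }).to_csv(paths["covariates"], index=False)
        pd.DataFrame({
            "species": [sp.name for sp in truth.species_params],
            "endemism": [sp.endemism for sp in truth.species_params],
            "habitat": [sp.habitat for sp in truth.species_params],
            "host_plant": [sp.host_plant for sp in truth.species_params],
        }).to_csv(paths["traits"], index=False)
        pd.DataFrame({
            "region": np.repeat(config.regions, T),
            "year": np.tile(config.years, R),
            "expected_richness": truth.expected_richness.ravel(),
        }).to_csv(paths["truth_richness"], index=False)
        S = config.n_species
        pd.DataFrame({
            "species": np.repeat([sp.name for sp in truth.species_params], R * T),
            "region": np.tile(np.repeat(config.regions, T), S),
            "year": np.tile(config.years, S * R),
            "z": truth.z.ravel(),
            "marginal_prob": truth.marginal_prob.ravel(),
        }).to_csv(paths["truth_states"], index=False)
        paths["config"].write_text(config.to_json())
    except OSError as exc:
        raise OSError(f"failed writing study bundle under {out}: {exc}") from exc
    return paths
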