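"""End-to-end orchestration: records -> occupancy fits -> richness -> trends.

Each stage reads and writes plain files inside a run directory, so a run can
be resumed or partially re-executed from intermediate artifacts and will
reproduce downstream outputs exactly.  Taxa are analysed separately
throughout (recording effort differs between them); species whose occupancy
model fails the goodness-of-fit check are excluded from the primary richness
analysis, with an optional sensitivity rerun that keeps them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataprep import (
    DetectionData,
    build_detection_data,
    covariates_from_frame,
    filter_species,
    load_covariates,
    load_records,
    load_traits,
    standardize_covariates,
)
from .occupancy import (
    CANDIDATE_DYNAMICS,
    OccupancyTrajectory,
    fit_species,
    gof_parametric_bootstrap,
    occupancy_trajectory,
)
from .synth import SimConfig, generate_study
from .trends import (
    DEFAULT_FORMS,
    DEFAULT_WINDOWS,
    RichnessSeries,
    decadal_slope,
    fit_trait_trend,
    fit_trend_suite,
    segment_trend,
    sum_richness,
    trait_richness,
    window_trends,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report",
           "stage_simulate", "stage_prepare", "stage_fit",
           "stage_richness", "stage_trends"]


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    # inputs: either a simulation config or paths to the three CSVs
    sim: SimConfig | None = None
    records: str | None = None
    covariates: str | None = None
    traits: str | None = None
    # dataprep
    span: tuple | None = None
    regions: list | None = None
    min_detection_years: int = 2
    burn_in_years: int = 4
    # occupancy
    candidates: tuple = CANDIDATE_DYNAMICS
    initial_occupancy: str = "fixed_one"
    trajectory_mode: str = "smoothed"
    n_restarts: int = 5
    gof_n_sim: int = 99
    gof_alpha: float = 0.05
    include_poor_fit: bool = False
    # trends
    trend_forms: tuple = DEFAULT_FORMS
    windows: tuple = DEFAULT_WINDOWS
    trait_columns: tuple = ("endemism", "habitat", "host_plant")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "trait_trend_shifts" in sim:
                sim["trait_trend_shifts"] = {
                    k: tuple(v) for k, v in sim["trait_trend_shifts"].items()}
            raw["sim"] = SimConfig(**sim)
        for key in ("span", "candidates", "trend_forms", "windows",
                    "trait_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _fail(out: Path, stage: str, exc: Exception):
    (out / "failed").write_text(f"stage={stage}\n{exc}\n")
    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# stages (file in, file out)


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    paths = generate_study(cfg.sim, out / "inputs")
    return {"records": paths["records"], "covariates": paths["covariates"],
            "traits": paths["traits"]}


def stage_prepare(cfg: PipelineConfig, out: Path, inputs: dict) -> list[str]:
    """Detection histories per taxon, written as tidy CSV."""
    records = load_records(inputs["records"])
    traits = load_traits(inputs["traits"]) if inputs.get("traits") else None
    taxa = sorted(records["taxon"].unique())
    for taxon in taxa:
        # the trait table defines the study species list; other records
        # (e.g. indeterminate specimens) still count toward effort
        species = None
        if traits is not None:
            in_taxon = set(records.loc[records["taxon"] == taxon, "species"])
            species = sorted(in_taxon & set(traits.index))
        data = build_detection_data(records, taxon, regions=cfg.regions,
                                    span=cfg.span, species=species or None)
        data = filter_species(data, cfg.min_detection_years)
        data.to_frame().to_csv(out / f"detection_{taxon}.csv", index=False)
    return taxa


def _load_detection(out: Path, taxon: str) -> DetectionData:
    return DetectionData.from_frame(pd.read_csv(out / f"detection_{taxon}.csv"))


def stage_fit(cfg: PipelineConfig, out: Path, inputs: dict, taxon: str) -> None:
    """Candidate fits, AIC selection, GOF and trajectories for one taxon."""
    data = _load_detection(out, taxon)
    cov = covariates_from_frame(load_covariates(inputs["covariates"]))
    cov = cov.subset_years(data.years)
    std = standardize_covariates(cov, data.effort)

    aic_rows, res_rows, traj_rows = [], [], []
    for i, sp in enumerate(data.species):
        best, table = fit_species(
            data, cov, std, sp, candidates=cfg.candidates,
            initial_occupancy=cfg.initial_occupancy,
            n_restarts=cfg.n_restarts, seed=cfg.seed + 1000 * i)
        gof = gof_parametric_bootstrap(best, n_sim=cfg.gof_n_sim,
                                       seed=cfg.seed + 1000 * i + 7,
                                       alpha=cfg.gof_alpha)
        table = table.assign(species=sp,
                             selected=table["dynamics"] == best.spec.dynamics)
        aic_rows.append(table)
        res_rows.append({
            "species": sp, "dynamics": best.spec.dynamics, "aic": best.aic,
            "loglik": best.loglik, "converged": best.converged,
            "gof_p": gof.p_value, "poor_fit": gof.poor_fit,
            "coef": json.dumps(dict(zip(best.coef_names, best.coef))),
            "se": json.dumps(dict(zip(best.coef_names, best.se))),
        })
        traj = occupancy_trajectory(best, mode=cfg.trajectory_mode,
                                    burn_in_years=cfg.burn_in_years)
        R, T = traj.prob.shape
        traj_rows.append(pd.DataFrame({
            "species": sp,
            "region": np.repeat(data.regions, T),
            "year": np.tile(traj.years, R),
            "prob": traj.prob.ravel(),
            "burn_in": np.tile(traj.burn_in, R),
        }))
        logger.info("fitted %s (%s): best=%s gof_p=%.3f", taxon, sp,
                    best.spec.dynamics, gof.p_value)
    pd.concat(aic_rows).to_csv(out / f"aic_table_{taxon}.csv", index=False)
    pd.DataFrame(res_rows).to_csv(out / f"species_results_{taxon}.csv",
                                  index=False)
    pd.concat(traj_rows).to_csv(out / f"trajectories_{taxon}.csv", index=False)


def _load_trajectories(out: Path, taxon: str) -> dict[str, OccupancyTrajectory]:
    df = pd.read_csv(out / f"trajectories_{taxon}.csv")
    trajs = {}
    for sp, g in df.groupby("species", sort=False):
        years = np.sort(g["year"].unique())
        regions = sorted(g["region"].unique())
        prob = (g.pivot(index="region", columns="year", values="prob")
                .loc[regions, years].to_numpy())
        burn = (g.pivot(index="region", columns="year", values="burn_in")
                .loc[regions, years].to_numpy()[0].astype(bool))
        trajs[sp] = OccupancyTrajectory(prob=prob, mode="loaded",
                                        years=years, burn_in=burn)
    return trajs


def stage_richness(cfg: PipelineConfig, out: Path, inputs: dict,
                   taxon: str) -> None:
    """Summed-occupancy richness: overall, per trait class, and sensitivity."""
    data = _load_detection(out, taxon)
    results = pd.read_csv(out / f"species_results_{taxon}.csv")
    trajs = _load_trajectories(out, taxon)
    traits = load_traits(inputs["traits"]) if inputs.get("traits") else None
    good = set(results.loc[~results["poor_fit"], "species"])
    primary = {s: t for s, t in trajs.items() if s in good}
    if not primary:
        raise ValueError(f"no well-fitting species for taxon {taxon}")

    def collect(traj_set, path):
        frames = []
        rs = sum_richness(traj_set, data.surveyed, data.regions)
        frames.append(rs.df.assign(subset="all", n_species=rs.n_species))
        if traits is not None:
            for col in cfg.trait_columns:
                try:
                    tr = trait_richness(traj_set, data.surveyed, data.regions,
                                        traits.loc[list(traj_set)], col)
                except (ValueError, KeyError) as exc:
                    logger.warning("taxon %s trait %s skipped: %s",
                                   taxon, col, exc)
                    continue
                frames.append(tr.df.assign(
                    subset=tr.df["trait"].map(lambda c: f"{col}={c}"),
                    n_species=tr.n_species).drop(columns="trait"))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    collect(primary, out / f"richness_{taxon}.csv")
    if cfg.include_poor_fit and len(primary) < len(trajs):
        collect(trajs, out / f"richness_sensitivity_{taxon}.csv")


def _trend_block(sr: RichnessSeries, cfg: PipelineConfig) -> dict:
    suite = fit_trend_suite(sr, forms=cfg.trend_forms)
    block = {
        "n_knots": suite.n_knots,
        "best_form": suite.best.form,
        "aic_table": suite.aic_table.to_dict("records"),
        "f_tests": suite.f_tests.to_dict("records"),
    }
    if "linear_interaction" in suite.fits:
        block["decadal_slopes"] = decadal_slope(
            suite.fits["linear_interaction"]).to_dict("records")
    if suite.best.is_smooth:
        segs = segment_trend(suite.best, sr)
        block["periods"] = {str(r): [dataclasses.asdict(p) for p in ps]
                            for r, ps in segs.items()}
    block["windows"] = window_trends(sr, cfg.windows).to_dict("records")
    return block


def stage_trends(cfg: PipelineConfig, out: Path, inputs: dict,
                 taxon: str, suffix: str = "") -> None:
    df = pd.read_csv(out / f"richness{suffix}_{taxon}.csv")
    report: dict = {"taxon": taxon, "seed": cfg.seed}
    all_df = df[df["subset"] == "all"]
    sr = RichnessSeries(all_df[["region", "year", "sr"]],
                        subset="all", n_species=int(all_df["n_species"].iloc[0]))
    report["all"] = _trend_block(sr, cfg)

    report["traits"] = {}
    for col in cfg.trait_columns:
        mask = df["subset"].str.startswith(f"{col}=")
        if not mask.any():
            continue
        sub = df[mask].copy()
        sub["trait"] = sub["subset"].str.split("=", n=1).str[1]
        sr_t = RichnessSeries(sub[["region", "year", "sr", "trait"]],
                              subset=col, n_species=int(sub["n_species"].max()))
        try:
            res = fit_trait_trend(sr_t)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("taxon %s trait trend %s skipped: %s", taxon, col, exc)
            continue
        report["traits"][col] = {
            "n_knots": res.n_knots,
            "best_form": res.best.form,
            "aic_table": res.aic_table.to_dict("records"),
            "interaction_f_test": res.interaction_f_test,
            "class_slopes": res.class_slopes.to_dict("records"),
        }
    (out / f"trends{suffix}_{taxon}.json").write_text(
        json.dumps(report, indent=2, default=float))


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "versions": {m.__name__: m.__version__
                     for m in (np, pd)},
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }
    stage = "simulate"
    try:
        if cfg.sim is not None:
            inputs = {k: str(v) for k, v in stage_simulate(cfg, out).items()}
        else:
            if not cfg.records or not cfg.covariates:
                raise ValueError("need either sim config or records+covariates")
            inputs = {"records": cfg.records, "covariates": cfg.covariates,
                      "traits": cfg.traits}
        manifest["inputs"] = inputs

        stage = "prepare"
        taxa = stage_prepare(cfg, out, inputs)
        manifest["taxa"] = taxa
        for taxon in taxa:
            manifest["stages"][taxon] = {}
            stage = f"fit[{taxon}]"
            stage_fit(cfg, out, inputs, taxon)
            res = pd.read_csv(out / f"species_results_{taxon}.csv")
            manifest["stages"][taxon]["n_species"] = len(res)
            manifest["stages"][taxon]["n_poor_fit"] = int(res["poor_fit"].sum())
            stage = f"richness[{taxon}]"
            stage_richness(cfg, out, inputs, taxon)
            manifest["stages"][taxon]["richness_rows"] = len(
                pd.read_csv(out / f"richness_{taxon}.csv"))
            stage = f"trends[{taxon}]"
            stage_trends(cfg, out, inputs, taxon)
            if (out / f"richness_sensitivity_{taxon}.csv").exists():
                stage_trends(cfg, out, inputs, taxon, suffix="_sensitivity")
    except Exception as exc:  # partial outputs stay under the failed marker
        _fail(out, stage, exc)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def _fmt_slope(row) -> str:
    arrow = {"increasing": "up", "decreasing": "down", "stable": "-"}
    return (f"{row['slope_per_decade']:+.3f} +/- {row['se']:.3f} "
            f"[{arrow.get(row['direction'], '?')}]")


def report(run_dir) -> str:
    """Human-readable summary of a completed run (per taxon and region)."""
    out = Path(run_dir)
    if not (out / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest in {run_dir}: incomplete run")
    manifest = json.loads((out / "manifest.json").read_text())
    lines = [f"occutrends run {manifest['config_hash']} (seed {manifest['seed']})"]
    for taxon in manifest.get("taxa", []):
        tpath = out / f"trends_{taxon}.json"
        if not tpath.exists():
            raise FileNotFoundError(f"missing trends output for {taxon}")
        tr = json.loads(tpath.read_text())
        lines.append(f"\n== {taxon} ==")
        lines.append(f"best richness model: {tr['all']['best_form']} "
                     f"(k={tr['all']['n_knots']})")
        lines.append("long-term change per decade (linear interaction model):")
        for row in tr["all"].get("decadal_slopes", []):
            lines.append(f"  region {row['region']}: {_fmt_slope(row)}")
        if "periods" in tr["all"]:
            lines.append("multi-decadal periods (best smooth model):")
            for r, ps in tr["all"]["periods"].items():
                for p in ps:
                    lines.append(
                        f"  region {r} {p['start']}-{p['end']}: "
                        f"{p['trend_per_decade']:+.3f} +/- {p['se']:.3f} "
                        f"[{p['direction']}]")
        lines.append("window sensitivity (slope per decade by series length):")
        for row in tr["all"]["windows"]:
            if row["available"]:
                lines.append(f"  past {row['window']} y, region {row['region']}: "
                             f"{_fmt_slope(row)}")
        if tr.get("traits"):
            for col, block in tr["traits"].items():
                f = block["interaction_f_test"]
                lines.append(f"trait {col}: best={block['best_form']}, "
                             f"interaction F={f['F']:.2f} (p={f['p']:.3g})")
                for row in block["class_slopes"]:
                    lines.append(f"  {row['trait']}, region {row['region']}: "
                                 f"{_fmt_slope(row)}")
        else:
            lines.append("trait analyses: not available")
    return "\n".join(lines)
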