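"""Richness series and trend analyses built on occupancy-model outputs.

Regional species richness for a year is the sum over species of their
estimated probability of occurrence.  Five Gaussian trend models (intercept
only, linear additive, linear interaction, nonlinear additive, nonlinear
interaction — smooths are penalized cubic regression splines) are compared by
AIC and approximate F-tests; linear-model slopes are reported per decade
(annual slope x 10) with a simple interval rule for direction: increasing or
decreasing when slope +/- SE excludes zero, stable otherwise.  Smooth fits
are segmented into maximal runs of constant first-derivative sign, and
trailing-window refits probe how trend estimates depend on series length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats

from ._pspline import AdditiveTrendModel, gaussian_aic
from .occupancy import OccupancyTrajectory

__all__ = [
    "RichnessSeries",
    "TrendFit",
    "TrendSuiteResult",
    "TrendPeriod",
    "sum_richness",
    "trait_richness",
    "fit_trend_suite",
    "decadal_slope",
    "classify_trend",
    "segment_trend",
    "window_trends",
    "fit_trait_trend",
    "DEFAULT_FORMS",
    "DEFAULT_WINDOWS",
]

logger = logging.getLogger(__name__)

DEFAULT_FORMS = (
    "intercept_only",
    "linear_additive",
    "linear_interaction",
    "nonlinear_additive",
    "nonlinear_interaction",
)
DEFAULT_WINDOWS = (10, 25, 50, 75, 100, 125, 150, "full")
KNOT_GRID = (5, 8, 10, 15)

_OLS_FORMULAS = {
    "intercept_only": "sr ~ C(region)",
    "linear_additive": "sr ~ year + C(region)",
    "linear_interaction": "sr ~ year * C(region)",
}


@dataclass
class RichnessSeries:
    """Summed-occupancy species richness per (region, year)."""

    df: pd.DataFrame  # columns: region, year, sr [, trait]
    subset: str
    n_species: int

    def __post_init__(self):
        if self.df.empty:
            raise ValueError(f"empty richness series for subset {self.subset!r}")
        if (self.df["sr"] < -1e-9).any() or (self.df["sr"] > self.n_species + 1e-9).any():
            raise ValueError("richness outside [0, n_species]")

    @property
    def regions(self) -> list:
        return sorted(self.df["region"].unique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.df["year"].unique())


def _resolve_subset(trajectories, subset, traits):
    names = list(trajectories)
    if subset == "all":
        return names
    col, value = subset
    if traits is None:
        raise ValueError("trait table required for a trait subset")
    missing = [s for s in names if s not in traits.index]
    if col == "endemism" and missing:
        raise KeyError(f"species missing endemism entries: {missing}")
    known = [s for s in names if s in traits.index and traits.loc[s, col] != "unknown"]
    dropped = len(names) - len(known)
    if dropped:
        logger.info("subset %s=%s: dropped %d species with unknown trait",
                    col, value, dropped)
    chosen = [s for s in known if traits.loc[s, col] == value]
    if not chosen:
        raise ValueError(f"no species with {col} == {value!r}")
    return chosen


def sum_richness(trajectories: dict[str, OccupancyTrajectory], surveyed,
                 regions, subset="all", traits: pd.DataFrame | None = None,
                 ) -> RichnessSeries:
    """Sum occurrence probabilities over species for each surveyed region-year.

    ``subset`` is "all" or a ``(trait_column, value)`` pair resolved through
    the trait table; burn-in years and unsurveyed region-years yield no rows.
    """
    chosen = _resolve_subset(trajectories, subset, traits)
    ref = trajectories[chosen[0]]
    total = np.zeros_like(ref.prob)
    for s in chosen:
        tr = trajectories[s]
        if not np.array_equal(tr.years, ref.years):
            raise ValueError("trajectories must share a year axis")
        total += tr.prob
    keep = np.asarray(surveyed, bool) & ~ref.burn_in[None, :]
    ri, ti = np.nonzero(keep)
    label = "all" if subset == "all" else f"{subset[0]}={subset[1]}"
    df = pd.DataFrame({
        "region": np.asarray(regions)[ri],
        "year": ref.years[ti],
        "sr": total[ri, ti],
    })
    return RichnessSeries(df=df, subset=label, n_species=len(chosen))


def trait_richness(trajectories, surveyed, regions, traits,
                   trait_col: str) -> RichnessSeries:
    """Stacked richness series for every known class of one trait column."""
    classes = [c for c in traits[trait_col].unique() if c != "unknown"]
    if len(classes) < 2:
        raise ValueError(
            f"trait {trait_col!r} needs >=2 known classes, found {classes}")
    parts = []
    for c in sorted(classes):
        rs = sum_richness(trajectories, surveyed, regions,
                          subset=(trait_col, c), traits=traits)
        part = rs.df.copy()
        part["trait"] = c
        parts.append(part)
    df = pd.concat(parts, ignore_index=True)
    n = sum(int((traits[trait_col] == c).sum()) for c in classes)
    return RichnessSeries(df=df, subset=trait_col, n_species=n)


# ---------------------------------------------------------------------------
# trend model suite


@dataclass
class TrendFit:
    form: str
    kind: str  # "ols" | "gam"
    model: object = field(repr=False)
    aic: float = np.nan
    rss: float = np.nan
    edf: float = np.nan
    n: int = 0
    year_range: tuple = (None, None)

    @property
    def is_smooth(self) -> bool:
        return self.kind == "gam"

    def predict(self, newdata: pd.DataFrame, cov: bool = False):
        """Mean prediction (and covariance) for rows of region/year (+trait)."""
        if self.kind == "gam":
            return self.model.predict(newdata, cov=cov)
        X0 = patsy.build_design_matrices(
            [self.model.model.data.design_info], newdata)[0]
        X0 = np.asarray(X0)
        mu = X0 @ self.model.params.to_numpy()
        if not cov:
            return mu
        V = self.model.cov_params().to_numpy()
        return mu, X0 @ V @ X0.T


def _fit_ols(form: str, df: pd.DataFrame, formula: str | None = None) -> TrendFit:
    res = smf.ols(formula or _OLS_FORMULAS[form], data=df).fit()
    n = int(res.nobs)
    k = len(res.params)
    rss = float(res.ssr)
    return TrendFit(form=form, kind="ols", model=res,
                    aic=gaussian_aic(n, rss, k), rss=rss, edf=float(k), n=n,
                    year_range=(df["year"].min(), df["year"].max()))


def _fit_gam(form: str, df: pd.DataFrame, n_knots: int,
             factors=("region",), smooths=(None,)) -> TrendFit:
    m = AdditiveTrendModel(df, "sr", x="year", factors=list(factors),
                           smooths=list(smooths), n_knots=n_knots).fit()
    return TrendFit(form=form, kind="gam", model=m, aic=m.aic, rss=m.rss,
                    edf=m.edf, n=m.n,
                    year_range=(df["year"].min(), df["year"].max()))


def select_knots(df: pd.DataFrame, grid=KNOT_GRID, factors=("region",),
                 smooths=(None,)) -> int | None:
    """Pick a basis dimension from the candidate grid by AIC.

    The grid is capped at half the number of unique years; the chosen value
    is then fixed for every smooth form of a model suite.
    """
    cap = df["year"].nunique() // 2
    candidates = [k for k in grid if k <= cap]
    if not candidates:
        return None
    best_k, best_aic = None, np.inf
    for k in candidates:
        try:
            fit = _fit_gam("_knots", df, k, factors, smooths)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if fit.aic < best_aic:
            best_k, best_aic = k, fit.aic
    return best_k


@dataclass
class TrendSuiteResult:
    fits: dict
    best: TrendFit
    aic_table: pd.DataFrame
    f_tests: pd.DataFrame
    n_knots: int | None


def _approx_f_test(lin: TrendFit, non: TrendFit) -> dict:
    df1 = non.edf - lin.edf
    df2 = non.n - non.edf
    if df1 <= 1e-8 or non.rss <= 0:
        return {"F": 0.0, "df1": max(df1, 0.0), "df2": df2, "p": 1.0}
    F = ((lin.rss - non.rss) / df1) / (non.rss / df2)
    F = max(F, 0.0)
    return {"F": F, "df1": df1, "df2": df2,
            "p": float(stats.f.sf(F, df1, df2))}


def fit_trend_suite(sr: RichnessSeries, forms=DEFAULT_FORMS,
                    knot_grid=KNOT_GRID) -> TrendSuiteResult:
    """Fit the candidate trend forms to one richness series, select by AIC.

    Approximate F-tests (EDF-based residual dfs) compare each nonlinear form
    with its nested linear counterpart.
    """
    df = sr.df
    n_regions = df["region"].nunique()
    if n_regions < 2:
        raise ValueError("need >= 2 regions")
    min_years = df.groupby("region")["year"].nunique().min()
    if min_years < 3:
        raise ValueError("need >= 3 observed years per region")

    n_knots = None
    if any(f.startswith("nonlinear") for f in forms):
        n_knots = select_knots(df, knot_grid)

    fits: dict[str, TrendFit] = {}
    for form in forms:
        try:
            if form in _OLS_FORMULAS:
                fits[form] = _fit_ols(form, df)
            elif form == "nonlinear_additive":
                if n_knots is None:
                    raise ValueError("too few years for a smooth")
                fits[form] = _fit_gam(form, df, n_knots)
            elif form == "nonlinear_interaction":
                if n_knots is None:
                    raise ValueError("too few years for a smooth")
                fits[form] = _fit_gam(form, df, n_knots, smooths=("region",))
            else:
                raise ValueError(f"unknown trend form {form!r}")
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"skipping trend form {form!r}: {exc}")
    if not fits:
        raise ValueError("no trend form could be fitted")

    table = pd.DataFrame({
        "form": list(fits),
        "aic": [f.aic for f in fits.values()],
        "edf": [f.edf for f in fits.values()],
        "rss": [f.rss for f in fits.values()],
    })
    table["delta_aic"] = table["aic"] - table["aic"].min()
    rows = []
    for lin_name, non_name in (("linear_additive", "nonlinear_additive"),
                               ("linear_interaction", "nonlinear_interaction")):
        if lin_name in fits and non_name in fits:
            rows.append({"comparison": f"{lin_name} vs {non_name}",
                         **_approx_f_test(fits[lin_name], fits[non_name])})
    best = min(fits.values(), key=lambda f: f.aic)
    return TrendSuiteResult(fits=fits, best=best, aic_table=table,
                            f_tests=pd.DataFrame(rows), n_knots=n_knots)


# ---------------------------------------------------------------------------
# slopes, classification, segmentation, windows


def classify_trend(estimate: float, se: float) -> str:
    """Direction call from the slope +/- SE interval against zero."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    if estimate - se > 0:
        return "increasing"
    if estimate + se < 0:
        return "decreasing"
    return "stable"


def _slope_contrast(fit: TrendFit, row: dict) -> tuple[float, float]:
    """Annual year-slope at a covariate setting via a unit-year design contrast."""
    lo = pd.DataFrame([row])
    hi = pd.DataFrame([{**row, "year": row["year"] + 1}])
    if fit.kind == "gam":
        raise ValueError("slope contrasts require a linear fit")
    di = fit.model.model.data.design_info
    X = np.asarray(patsy.build_design_matrices([di], pd.concat([lo, hi]))[0])
    c = X[1] - X[0]
    est = float(c @ fit.model.params.to_numpy())
    se = float(np.sqrt(c @ fit.model.cov_params().to_numpy() @ c))
    return est, se


def decadal_slope(fit: TrendFit, regions=None) -> pd.DataFrame:
    """Per-region per-decade slope (annual slope x 10) with SE and direction."""
    if fit.form not in ("linear_additive", "linear_interaction"):
        raise ValueError(f"form {fit.form!r} has no linear year term")
    if regions is None:
        regions = sorted(fit.model.model.data.frame["region"].unique())
    y0 = fit.year_range[0]
    rows = []
    for r in regions:
        est, se = _slope_contrast(fit, {"region": r, "year": y0})
        rows.append({"region": r, "slope_per_decade": 10 * est, "se": 10 * se,
                     "direction": classify_trend(10 * est, 10 * se)})
    return pd.DataFrame(rows)


@dataclass
class TrendPeriod:
    start: int
    end: int
    trend_per_decade: float
    se: float
    direction: str


def segment_trend(fit: TrendFit, sr: RichnessSeries) -> dict:
    """Split a smooth fit into maximal runs of constant derivative sign.

    Predictions are made on the integer year grid spanning the series; the
    discrete derivative is the year-to-year difference of predicted values
    (zero differences extend the current run).  Each period's trend is
    (yhat_end - yhat_start) / (end - start) x 10 per decade, with SE by the
    delta method from the prediction covariance.
    """
    if not fit.is_smooth:
        raise ValueError("segmentation requires a smooth (nonlinear) fit")
    years = np.arange(int(sr.years.min()), int(sr.years.max()) + 1)
    if len(years) < 3:
        raise ValueError("need >= 3 grid years to segment")
    out = {}
    for r in sr.regions:
        grid = pd.DataFrame({"region": r, "year": years})
        mu, V = fit.predict(grid, cov=True)
        d = np.diff(mu)
        sgn = np.sign(d)
        breaks = [0]
        cur = 0.0
        for i, v in enumerate(sgn):
            if v != 0 and cur != 0 and v != cur:
                breaks.append(i)
            if v != 0:
                cur = v
        breaks.append(len(years) - 1)
        periods = []
        for i0, i1 in zip(breaks[:-1], breaks[1:]):
            span = years[i1] - years[i0]
            est = (mu[i1] - mu[i0]) / span * 10.0
            var = V[i1, i1] + V[i0, i0] - 2.0 * V[i0, i1]
            se = float(np.sqrt(max(var, 0.0))) / span * 10.0
            periods.append(TrendPeriod(
                start=int(years[i0]), end=int(years[i1]),
                trend_per_decade=float(est), se=se,
                direction=classify_trend(est, se)))
        out[r] = periods
    return out


def window_trends(sr: RichnessSeries, windows=DEFAULT_WINDOWS) -> pd.DataFrame:
    """Refit the linear interaction model on trailing windows of the series.

    Each window covers the most recent ``L`` years; regions with fewer than 3
    observed years inside a window are reported as unavailable.  The
    ``overlaps_full`` column says whether the window's slope +/- SE interval
    intersects the full-span interval for that region.
    """
    last = int(sr.df["year"].max())
    full_span = last - int(sr.df["year"].min()) + 1
    full_fit = _fit_ols("linear_interaction", sr.df)
    full_slopes = decadal_slope(full_fit, sr.regions).set_index("region")
    rows = []
    for w in windows:
        length = full_span if w == "full" else int(w)
        if length > full_span:
            warnings.warn(f"window {w} exceeds the span ({full_span} years); "
                          "marked unavailable")
            rows += [{"window": w, "region": r, "slope_per_decade": np.nan,
                      "se": np.nan, "direction": "unavailable",
                      "available": False, "overlaps_full": np.nan}
                     for r in sr.regions]
            continue
        sub = sr.df[sr.df["year"] > last - length]
        counts = sub.groupby("region")["year"].nunique()
        usable = [r for r in sr.regions if counts.get(r, 0) >= 3]
        slopes = None
        if len(usable) >= 1:
            sub_use = sub[sub["region"].isin(usable)]
            formula = ("sr ~ year * C(region)" if len(usable) > 1
                       else "sr ~ year")
            fit = _fit_ols("linear_interaction", sub_use, formula=formula)
            slopes = decadal_slope(fit, usable).set_index("region")
        for r in sr.regions:
            if slopes is not None and r in slopes.index:
                est = slopes.loc[r, "slope_per_decade"]
                se = slopes.loc[r, "se"]
                fe, fs = (full_slopes.loc[r, "slope_per_decade"],
                          full_slopes.loc[r, "se"])
                overlaps = (est - se) <= (fe + fs) and (fe - fs) <= (est + se)
                rows.append({"window": w, "region": r, "slope_per_decade": est,
                             "se": se, "direction": classify_trend(est, se),
                             "available": True, "overlaps_full": overlaps})
            else:
                rows.append({"window": w, "region": r,
                             "slope_per_decade": np.nan, "se": np.nan,
                             "direction": "unavailable", "available": False,
                             "overlaps_full": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait-stratified trends


@dataclass
class TraitTrendResult:
    fits: dict
    best: TrendFit
    aic_table: pd.DataFrame
    interaction_f_test: dict
    class_slopes: pd.DataFrame
    n_knots: int | None


def fit_trait_trend(sr: RichnessSeries, knot_grid=KNOT_GRID) -> TraitTrendResult:
    """Compare trait-stratified trend models on a stacked two-class series.

    Candidates: a linear year x region + year x trait model, a nonlinear
    model ignoring trait, and a nonlinear model with an extra by-trait
    smooth.  The trait-interaction F-test compares the two nonlinear fits;
    per-class per-decade slopes follow the linear interaction convention.
    """
    df = sr.df
    if "trait" not in df.columns or df["trait"].nunique() < 2:
        raise ValueError("need a stacked richness series with >= 2 trait classes")

    n_knots = select_knots(df, knot_grid, factors=("region", "trait"),
                           smooths=("region",))
    fits: dict[str, TrendFit] = {}
    fits["linear_interaction"] = _fit_ols(
        "linear_interaction", df, formula="sr ~ year * C(region) + year * C(trait)")
    if n_knots is not None:
        fits["nonlinear_simple"] = _fit_gam(
            "nonlinear_simple", df, n_knots,
            factors=("region",), smooths=("region",))
        # the by-region smooths keep the penalty selected under the simple
        # model, so the nested F-test charges only the trait terms
        simple = fits["nonlinear_simple"].model
        inter = AdditiveTrendModel(
            df, "sr", x="year", factors=["region", "trait"],
            smooths=["region", "trait"], n_knots=n_knots)
        inter.fit(fixed_lambdas=dict(enumerate(simple.lambdas)))
        fits["nonlinear_interaction"] = TrendFit(
            form="nonlinear_interaction", kind="gam", model=inter,
            aic=inter.aic, rss=inter.rss, edf=inter.edf, n=inter.n,
            year_range=(df["year"].min(), df["year"].max()))
    table = pd.DataFrame({"form": list(fits),
                          "aic": [f.aic for f in fits.values()],
                          "edf": [f.edf for f in fits.values()]})
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best = min(fits.values(), key=lambda f: f.aic)
    if "nonlinear_interaction" in fits:
        # reference-df convention: the added trait terms are charged their
        # full nominal column count, not their (adaptively shrunk) EDF —
        # deliberately conservative given GCV-selected penalties
        s, n_fit = fits["nonlinear_simple"], fits["nonlinear_interaction"]
        df1 = float(n_fit.model.X.shape[1] - s.model.X.shape[1])
        df2 = n_fit.n - n_fit.edf
        F = max((s.rss - n_fit.rss) / df1, 0.0) / (n_fit.rss / df2)
        ftest = {"F": F, "df1": df1, "df2": df2,
                 "p": float(stats.f.sf(F, df1, df2))}
    else:
        ftest = {"F": np.nan, "df1": np.nan, "df2": np.nan, "p": np.nan}

    lin = fits["linear_interaction"]
    y0 = df["year"].min()
    rows = []
    for c in sorted(df["trait"].unique()):
        for r in sorted(df["region"].unique()):
            est, se = _slope_contrast(lin, {"region": r, "trait": c, "year": y0})
            rows.append({"trait": c, "region": r,
                         "slope_per_decade": 10 * est, "se": 10 * se,
                         "direction": classify_trend(10 * est, 10 * se)})
    return TraitTrendResult(fits=fits, best=best, aic_table=table,
                            interaction_f_test=ftest,
                            class_slopes=pd.DataFrame(rows), n_knots=n_knots)
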