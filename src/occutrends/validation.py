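"""Replicated simulation studies that score the estimators against truth.

Each routine here sets up a small synthetic study from :mod:`occutrends.synth`
(or a constructed deterministic series), runs the estimation machinery the
package's users would run, and reports a summary number: an oracle agreement
error, a coverage rate, a selection rate, a type-I error, and so on.  They
are used by the test suite and by ``scripts/acceptance.py``; problem sizes
are chosen so a full set of replicates runs on one CPU in a few minutes
(see docs/methods.md for the study conditions).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.special import expit

from ._hmm import forward_nll
from .dataprep import standardize_covariates
from .occupancy import (
    OccupancyModelSpec,
    build_design,
    fit_occupancy,
    fit_species,
    gof_parametric_bootstrap,
    occupancy_trajectory,
)
from .synth import SimConfig, SpeciesParams, generate_covariates, simulate_detection_history
from .trends import (
    RichnessSeries,
    classify_trend,
    decadal_slope,
    fit_trend_suite,
    segment_trend,
    sum_richness,
    window_trends,
)

# Published long-term per-decade slope estimates (+/- SE) for two butterfly
# taxa across three Sulawesi study regions: the worked example for the
# interval-overlap direction rule.
PUBLISHED_LONGTERM_SLOPES = [
    # (taxon, region, slope_per_decade, se)
    ("Papilionidae", 1, +0.021, 0.025),
    ("Papilionidae", 2, +0.032, 0.025),
    ("Papilionidae", 3, +0.037, 0.025),
    ("Satyrinae", 1, +0.183, 0.089),
    ("Satyrinae", 2, +0.023, 0.089),
    ("Satyrinae", 3, +0.048, 0.089),
]


def published_direction_calls() -> dict:
    """Apply the SE-overlap direction rule to the published slope table."""
    calls = [classify_trend(est, se)
             for _, _, est, se in PUBLISHED_LONGTERM_SLOPES]
    return {
        "increasing": calls.count("increasing"),
        "stable": calls.count("stable"),
        "decreasing": calls.count("decreasing"),
        "n": len(calls),
        "calls": calls,
    }


# ---------------------------------------------------------------------------
# likelihood oracle


def enumerate_likelihood(y, p, gamma, eps, psi1) -> float:
    """Brute-force likelihood by summing over every latent state chain.

    Exponential in T; usable only for tiny instances, which is the point:
    it shares no code with the forward recursion it cross-checks.
    """
    y = np.atleast_2d(y)
    p, gamma, eps = np.atleast_2d(p), np.atleast_2d(gamma), np.atleast_2d(eps)
    R, T = y.shape
    total = 1.0
    for r in range(R):
        lik = 0.0
        for z in itertools.product((0, 1), repeat=T):
            pr = psi1 if z[0] == 1 else 1.0 - psi1
            for t in range(1, T):
                if z[t - 1] == 0:
                    pr *= gamma[r, t] if z[t] == 1 else 1.0 - gamma[r, t]
                else:
                    pr *= eps[r, t] if z[t] == 0 else 1.0 - eps[r, t]
            for t in range(T):
                if y[r, t] < 0:
                    continue
                pe = p[r, t] if z[t] == 1 else 0.0
                pr *= pe if y[r, t] == 1 else 1.0 - pe
            lik += pr
        total *= lik
    return total


def likelihood_oracle_check(seed: int = 0, n_instances: int = 100,
                            t_max: int = 6) -> dict:
    """Forward-algorithm likelihood vs exhaustive enumeration, tiny instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_done = 0
    while n_done < n_instances:
        T = int(rng.integers(1, t_max + 1))
        R = int(rng.integers(1, 4))
        p = rng.uniform(0.05, 0.95, (R, T))
        gamma = rng.uniform(0.05, 0.95, (R, T))
        eps = rng.uniform(0.05, 0.95, (R, T))
        psi1 = float(rng.uniform(0.05, 1.0))
        y = rng.integers(-1, 2, size=(R, T)).astype(np.int8)
        ref = enumerate_likelihood(y, p, gamma, eps, psi1)
        if ref <= 0.0:  # impossible history (e.g. detection at psi1-zero start)
            continue
        fwd = float(np.exp(-forward_nll(np.ascontiguousarray(y), p, gamma,
                                        eps, psi1)))
        worst = max(worst, abs(fwd - ref) / ref)
        n_done += 1
    return {"max_rel_error": worst, "n": n_instances}


# ---------------------------------------------------------------------------
# parameter recovery (constant dynamics, effort-linked detection)


def _single_species_config(seed, n_regions, n_years, params: SpeciesParams,
                           **kw) -> SimConfig:
    return SimConfig(n_species=1, n_regions=n_regions, n_years=n_years,
                     start_year=1900, species_params=[params], seed=seed, **kw)


def parameter_recovery(seed: int = 0, n_reps: int = 100, n_regions: int = 50,
                       n_years: int = 60) -> dict:
    """Refit the constant-dynamics model on replicate simulated studies.

    Truth: gamma = 0.4, eps = 0.3, detection logit-linear in standardized
    log effort (slope 1).  A replicate succeeds when every probability-scale
    parameter (gamma, eps, and p at mean log effort) lies within 3 estimated
    SEs of its true value, SEs mapped through the delta method.
    """
    truth = SpeciesParams(name="sp", gamma_intercept=float(np.log(0.4 / 0.6)),
                          eps_intercept=float(np.log(0.3 / 0.7)),
                          p_intercept=-0.4, p_effort=1.0)
    true_prob = {"gamma_intercept": 0.4, "eps_intercept": 0.3,
                 "p_intercept": float(expit(truth.p_intercept))}
    spec = OccupancyModelSpec(dynamics="constant")
    n_ok = 0
    for rep in range(n_reps):
        cfg = _single_species_config(seed + rep, n_regions, n_years, truth)
        data, _ = simulate_detection_history(cfg)
        cov = generate_covariates(cfg)
        std = standardize_covariates(cov, data.effort)
        design = build_design(spec, data, cov, std, "sp")
        fit = fit_occupancy(spec, design, n_restarts=2, seed=seed + rep)
        if fit.vcov is None:
            continue
        ok = True
        for name, target in true_prob.items():
            i = fit.coef_names.index(name)
            est = float(expit(fit.coef[i]))
            se = fit.se[i] * est * (1.0 - est)  # delta method to probability
            if se == 0 or abs(est - target) > 3.0 * se:
                ok = False
        n_ok += ok
    return {"within_3se_rate": n_ok / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# AIC covariate-selection consistency


def selection_consistency(seed: int = 0, n_reps: int = 200,
                          n_regions: int = 50, n_years: int = 60) -> dict:
    """How often AIC picks the true (forest) dynamics covariate.

    Truth has a strong forest-cover effect: logit slope +2 on colonization
    and -2 on extinction, with the forest decline placed inside the span so
    the covariate actually varies.
    """
    truth = SpeciesParams(name="sp", gamma_intercept=-1.0, gamma_slope=2.0,
                          eps_intercept=-1.0, eps_slope=-2.0,
                          p_intercept=0.0, p_effort=1.0, dynamics="forest")
    n_forest = 0
    n_done = 0
    for rep in range(n_reps):
        cfg = _single_species_config(
            seed + rep, n_regions, n_years, truth,
            forest_midpoint=n_years / 2, forest_rate=0.2)
        data, _ = simulate_detection_history(cfg)
        cov = generate_covariates(cfg)
        std = standardize_covariates(cov, data.effort)
        best, _ = fit_species(data, cov, std, "sp", n_restarts=2,
                              seed=seed + rep)
        n_forest += best.spec.dynamics == "forest"
        n_done += 1
    return {"forest_selected_rate": n_forest / n_done, "n": n_done}


# ---------------------------------------------------------------------------
# GOF calibration


def gof_type1_error(seed: int = 0, n_reps: int = 500, n_sim: int = 99,
                    alpha: float = 0.05, n_regions: int = 10,
                    n_years: int = 30) -> dict:
    """Rejection rate of the bootstrap GOF when the fitted model is true."""
    truth = SpeciesParams(name="sp", gamma_intercept=-0.5, eps_intercept=-1.0,
                          p_intercept=0.0, p_effort=1.0)
    spec = OccupancyModelSpec(dynamics="constant")
    n_reject = 0
    for rep in range(n_reps):
        cfg = _single_species_config(seed + rep, n_regions, n_years, truth)
        data, _ = simulate_detection_history(cfg)
        cov = generate_covariates(cfg)
        std = standardize_covariates(cov, data.effort)
        design = build_design(spec, data, cov, std, "sp")
        fit = fit_occupancy(spec, design, n_restarts=2, seed=seed + rep,
                            compute_vcov=False)
        g = gof_parametric_bootstrap(fit, n_sim=n_sim, seed=seed + rep,
                                     alpha=alpha)
        n_reject += g.poor_fit
    return {"type1_error": n_reject / n_reps, "n": n_reps,
            "n_sim": n_sim, "alpha": alpha}


# ---------------------------------------------------------------------------
# end-to-end richness trend recovery


def declining_community_config(seed: int, n_species: int = 12,
                               n_regions: int = 3,
                               n_years: int = 70) -> SimConfig:
    """A community whose expected richness declines close to -0.5/decade.

    Every species starts occupied (psi1 = 1) with slow dynamics whose
    equilibrium occupancy sits well below 1, so summed expected occupancy
    relaxes downward over the span; rates are set so the linear slope of
    true expected richness is about -0.05/year.
    """
    species = [SpeciesParams(name=f"sp_{i:02d}",
                             gamma_intercept=-4.0, eps_intercept=-4.5,
                             p_intercept=-0.2, p_effort=1.0)
               for i in range(n_species)]
    return SimConfig(n_species=n_species, n_regions=n_regions,
                     n_years=n_years, start_year=1900,
                     species_params=species, seed=seed)


def richness_trend_recovery(seed: int = 0, n_reps: int = 50,
                            burn_in_years: int = 4) -> dict:
    """Full pipeline on replicate declining communities.

    Per replicate: fit all candidate models per species, sum smoothed
    occupancy into a richness series, fit the linear additive trend, and ask
    whether its 95% CI (slope +/- 1.96 SE, per decade) covers the slope of
    the same linear model fitted to the analytic expected richness on the
    same observed region-years.
    """
    n_cover = 0
    true_slopes, est_slopes, tracking_r = [], [], []
    for rep in range(n_reps):
        cfg = declining_community_config(seed + rep)
        data, truth = simulate_detection_history(cfg)
        cov = generate_covariates(cfg)
        std = standardize_covariates(cov, data.effort)
        trajs = {}
        for i, sp in enumerate(data.species):
            best, _ = fit_species(data, cov, std, sp, n_restarts=2,
                                  seed=seed + rep + 97 * i)
            trajs[sp] = occupancy_trajectory(best, burn_in_years=burn_in_years)
        sr = sum_richness(trajs, data.surveyed, data.regions)
        est_fit = smf.ols("sr ~ year + C(region)", data=sr.df).fit()
        est = 10.0 * est_fit.params["year"]
        se = 10.0 * est_fit.bse["year"]

        # truth on the same observed rows
        tdf = sr.df.copy()
        ridx = {r: i for i, r in enumerate(data.regions)}
        yidx = {y: i for i, y in enumerate(data.years)}
        tdf["sr"] = [truth.expected_richness[ridx[r], yidx[y]]
                     for r, y in zip(tdf["region"], tdf["year"])]
        true_fit = smf.ols("sr ~ year + C(region)", data=tdf).fit()
        true_slope = 10.0 * true_fit.params["year"]

        n_cover += abs(est - true_slope) <= 1.96 * se
        true_slopes.append(true_slope)
        est_slopes.append(est)
        tracking_r.append(float(np.corrcoef(sr.df["sr"], tdf["sr"])[0, 1]))
    return {
        "coverage_rate": n_cover / n_reps,
        "n": n_reps,
        "mean_true_slope_per_decade": float(np.mean(true_slopes)),
        "mean_est_slope_per_decade": float(np.mean(est_slopes)),
        "mean_tracking_correlation": float(np.mean(tracking_r)),
    }


# ---------------------------------------------------------------------------
# segmentation and window checks on constructed series


def _two_region_series(years, f) -> RichnessSeries:
    rows = [{"region": r, "year": y, "sr": f(y) + (r - 1) * 0.5}
            for r in (1, 2) for y in years]
    return RichnessSeries(pd.DataFrame(rows), subset="all", n_species=30)


def segmentation_check(peak_year: int = 1930) -> dict:
    """Smooth fit to a noiseless unimodal series: expect one break at the peak.

    Also recomputes each reported period trend by hand from the predicted
    endpoint values, which must match the segmentation arithmetic exactly.
    """
    years = np.arange(1900, 1961)
    sr = _two_region_series(years, lambda y: 10.0 - 0.004 * (y - peak_year) ** 2)
    suite = fit_trend_suite(sr, forms=("linear_additive", "nonlinear_additive"))
    segs = segment_trend(suite.fits["nonlinear_additive"], sr)
    periods = segs[1]
    grid = pd.DataFrame({"region": 1, "year": np.arange(1900, 1961)})
    mu = suite.fits["nonlinear_additive"].predict(grid)
    ygrid = grid["year"].to_numpy()
    arith_err = 0.0
    for p in periods:
        i0, i1 = np.searchsorted(ygrid, [p.start, p.end])
        hand = (mu[i1] - mu[i0]) / (p.end - p.start) * 10.0
        arith_err = max(arith_err, abs(hand - p.trend_per_decade))
    breaks = [p.end for p in periods[:-1]]
    return {
        "n_periods": len(periods),
        "break_error_years": (abs(breaks[0] - peak_year)
                              if len(breaks) == 1 else np.inf),
        "directions": [p.direction for p in periods],
        "arithmetic_max_abs_error": arith_err,
    }


def window_check() -> dict:
    """Window refits on exactly linear data, then on a line + recent bump."""
    years = np.arange(1900, 2001)
    lin = _two_region_series(years, lambda y: 5.0 + 0.02 * (y - 1900))
    wt = window_trends(lin, windows=(10, 25, 50, "full"))
    avail = wt[wt["available"]]
    spread = float(avail["slope_per_decade"].max()
                   - avail["slope_per_decade"].min())

    bump = _two_region_series(
        years, lambda y: 20.0 - 0.03 * (y - 1900)
        + (0.5 * (y - 1990) if y > 1990 else 0.0))
    wb = window_trends(bump, windows=(10, "full"))
    wb = wb[wb["available"]].set_index(["window", "region"])
    recent = wb.loc[(10, 1), "slope_per_decade"]
    full = wb.loc[("full", 1), "slope_per_decade"]
    return {
        "linear_slope_spread": spread,
        "recent_slope": float(recent),
        "full_slope": float(full),
        "sign_flip": bool(np.sign(recent) != np.sign(full)),
    }
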