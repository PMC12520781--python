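import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occutrends.trends import (
    RichnessSeries,
    classify_trend,
    decadal_slope,
    fit_trait_trend,
    fit_trend_suite,
    segment_trend,
    sum_richness,
    trait_richness,
    window_trends,
)


def _series(years, f, regions=(1, 2), offset=0.5, trait=None):
    rows = []
    for r in regions:
        for y in years:
            row = {"region": r, "year": y,
                   "sr": f(y) + (r - regions[0]) * offset}
            if trait is not None:
                row["trait"] = trait
            rows.append(row)
    return pd.DataFrame(rows)


def _rs(df, n_species=30):
    return RichnessSeries(df, subset="all", n_species=n_species)


class TestSumRichness:
    def test_probabilities_add(self, fitted_study):
        data = study_data = fitted_study["data"]
        trajs = fitted_study["trajectories"]
        sr = sum_richness(trajs, data.surveyed, data.regions)
        # manual recomputation for one surveyed, post-burn-in cell
        row = sr.df.iloc[len(sr.df) // 2]
        r = data.regions.index(row["region"])
        t = list(data.years).index(row["year"])
        manual = sum(tr.prob[r, t] for tr in trajs.values())
        assert row["sr"] == pytest.approx(manual, abs=1e-12)
        assert (sr.df["sr"] <= len(trajs) + 1e-9).all()

    def test_trait_subset_equals_manual_sum(self, fitted_study, traits_frame):
        data = fitted_study["data"]
        trajs = fitted_study["trajectories"]
        sr = sum_richness(trajs, data.surveyed, data.regions,
                          subset=("endemism", "endemic"), traits=traits_frame)
        flagged = [s for s in trajs
                   if traits_frame.loc[s, "endemism"] == "endemic"]
        assert sr.n_species == len(flagged)
        row = sr.df.iloc[0]
        r = data.regions.index(row["region"])
        t = list(data.years).index(row["year"])
        manual = sum(trajs[s].prob[r, t] for s in flagged)
        assert row["sr"] == pytest.approx(manual, abs=1e-12)

    def test_burn_in_years_excluded(self, fitted_study):
        data = fitted_study["data"]
        sr = sum_richness(fitted_study["trajectories"], data.surveyed,
                          data.regions)
        burn_years = data.years[:4]
        assert not sr.df["year"].isin(burn_years).any()

    def test_empty_subset_errors(self, fitted_study, traits_frame):
        data = fitted_study["data"]
        with pytest.raises(ValueError, match="no species with"):
            sum_richness(fitted_study["trajectories"], data.surveyed,
                         data.regions, subset=("endemism", "martian"),
                         traits=traits_frame)

    def test_single_class_trait_errors(self, fitted_study, traits_frame):
        data = fitted_study["data"]
        mono = traits_frame.copy()
        mono["endemism"] = "endemic"
        with pytest.raises(ValueError, match=">=2 known classes"):
            trait_richness(fitted_study["trajectories"], data.surveyed,
                           data.regions, mono, "endemism")


class TestClassifyTrend:
    @pytest.mark.parametrize("est,se,want", [
        (+0.021, 0.025, "stable"),
        (+0.183, 0.089, "increasing"),
        (-1.185, 0.434, "decreasing"),
        (0.0, 0.0, "stable"),      # degenerate interval {0} touches zero
        (0.025, 0.025, "stable"),  # interval endpoint exactly at zero
    ])
    def test_interval_rule(self, est, se, want):
        assert classify_trend(est, se) == want

    @settings(derandomize=True, max_examples=60)
    @given(est=st.floats(-10, 10), se=st.floats(0, 5))
    def test_antisymmetric(self, est, se):
        mirror = {"increasing": "decreasing", "decreasing": "increasing",
                  "stable": "stable"}
        assert classify_trend(-est, se) == mirror[classify_trend(est, se)]

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            classify_trend(0.1, -0.1)


class TestTrendSuite:
    def test_exact_linear_data_recovered(self):
        years = np.arange(1900, 1980)
        sr = _rs(_series(years, lambda y: 4.0 + 0.0021 * (y - 1900)))
        suite = fit_trend_suite(sr)
        slopes = decadal_slope(suite.fits["linear_additive"])
        np.testing.assert_allclose(slopes["slope_per_decade"], 0.021,
                                   atol=1e-10)
        np.testing.assert_allclose(slopes["se"], 0.0, atol=1e-8)
        # the smooth's predictions also reproduce the line
        grid = pd.DataFrame({"region": 1, "year": years})
        mu = suite.fits["nonlinear_additive"].predict(grid)
        np.testing.assert_allclose(
            mu, 4.0 + 0.0021 * (years - 1900), atol=1e-6)

    def test_intercept_only_on_region_constant_data(self):
        years = np.arange(1900, 1930)
        sr = _rs(_series(years, lambda y: 7.0, offset=2.0))
        suite = fit_trend_suite(sr, forms=("intercept_only",))
        f = suite.fits["intercept_only"]
        assert f.rss == pytest.approx(0.0, abs=1e-18)
        with pytest.raises(ValueError, match="no linear year term"):
            decadal_slope(f)

    def test_nonlinear_wins_on_curved_signal(self):
        rng = np.random.default_rng(0)
        years = np.arange(1900, 2000)
        n_win = 0
        for rep in range(100):
            c = ((years - 1950) / 50.0)
            noise = rng.normal(0, 0.15, size=2 * len(years))
            df = _series(years, lambda y: 0.0)
            df["sr"] = np.tile(2.0 + c**3 - 0.5 * c, 2) + noise + \
                (df["region"] - 1) * 0.5
            suite = fit_trend_suite(
                _rs(df), forms=("linear_additive", "nonlinear_additive"))
            n_win += (suite.fits["nonlinear_additive"].aic
                      < suite.fits["linear_additive"].aic)
        assert n_win >= 95

    def test_decadal_slope_scales_linearly(self):
        years = np.arange(1900, 1960)
        rng = np.random.default_rng(1)
        df = _series(years, lambda y: 5 + 0.01 * (y - 1900))
        df["sr"] += rng.normal(0, 0.3, len(df))
        df2 = df.copy()
        df2["sr"] *= 3.0
        s1 = decadal_slope(fit_trend_suite(
            _rs(df), forms=("linear_interaction",)).fits["linear_interaction"])
        s2 = decadal_slope(fit_trend_suite(
            _rs(df2), forms=("linear_interaction",)).fits["linear_interaction"])
        np.testing.assert_allclose(3 * s1["slope_per_decade"],
                                   s2["slope_per_decade"], rtol=1e-9)
        np.testing.assert_allclose(3 * s1["se"], s2["se"], rtol=1e-9)

    def test_f_test_reported_for_nested_pairs(self, fitted_study):
        data = fitted_study["data"]
        sr = sum_richness(fitted_study["trajectories"], data.surveyed,
                          data.regions)
        suite = fit_trend_suite(sr)
        assert len(suite.f_tests) == 2
        assert ((suite.f_tests["p"] >= 0) & (suite.f_tests["p"] <= 1)).all()
        assert suite.best.aic == suite.aic_table["aic"].min()


class TestSegmentation:
    def test_unimodal_curve_splits_at_peak(self):
        years = np.arange(1900, 1961)
        sr = _rs(_series(years, lambda y: 10 - 0.004 * (y - 1930) ** 2))
        suite = fit_trend_suite(sr, forms=("nonlinear_additive",))
        segs = segment_trend(suite.best, sr)
        for r in (1, 2):
            assert len(segs[r]) == 2
            assert segs[r][0].end == 1930
            assert segs[r][1].start == 1930
            assert [p.direction for p in segs[r]] == ["increasing",
                                                      "decreasing"]

    def test_periods_tile_and_telescope(self, fitted_study):
        data = fitted_study["data"]
        sr = sum_richness(fitted_study["trajectories"], data.surveyed,
                          data.regions)
        suite = fit_trend_suite(sr, forms=("nonlinear_interaction",))
        segs = segment_trend(suite.best, sr)
        for r, periods in segs.items():
            assert periods[0].start == sr.years.min()
            assert periods[-1].end == sr.years.max()
            for a, b in zip(periods[:-1], periods[1:]):
                assert a.end == b.start
            # endpoint differences telescope to the total change
            grid = pd.DataFrame({"region": r,
                                 "year": np.arange(sr.years.min(),
                                                   sr.years.max() + 1)})
            mu = suite.best.predict(grid)
            total = sum(p.trend_per_decade / 10 * (p.end - p.start)
                        for p in periods)
            assert total == pytest.approx(mu[-1] - mu[0], abs=1e-9)

    def test_period_arithmetic(self):
        # 10 -> 12 over 20 years is +1.0 per decade
        years = np.arange(2000, 2021)
        sr = _rs(_series(years, lambda y: 10 + 0.1 * (y - 2000)))
        suite = fit_trend_suite(sr, forms=("nonlinear_additive",))
        segs = segment_trend(suite.best, sr)
        (p,) = segs[1]
        assert (p.start, p.end) == (2000, 2020)
        assert p.trend_per_decade == pytest.approx(1.0, abs=1e-4)
        # exact period arithmetic against the fit's own predictions
        grid = pd.DataFrame({"region": 1, "year": years})
        mu = suite.best.predict(grid)
        assert p.trend_per_decade == pytest.approx(
            (mu[-1] - mu[0]) / 20 * 10, abs=1e-12)

    def test_monotone_signal_is_single_period(self):
        years = np.arange(1900, 1981)
        sr = _rs(_series(years, lambda y: np.exp(0.01 * (y - 1900))))
        suite = fit_trend_suite(sr, forms=("nonlinear_additive",))
        segs = segment_trend(suite.best, sr)
        assert len(segs[1]) == 1
        assert segs[1][0].direction == "increasing"

    def test_requires_smooth_fit(self):
        years = np.arange(1900, 1930)
        sr = _rs(_series(years, lambda y: 0.1 * (y - 1900)))
        suite = fit_trend_suite(sr, forms=("linear_additive",))
        with pytest.raises(ValueError, match="smooth"):
            segment_trend(suite.fits["linear_additive"], sr)


class TestWindowTrends:
    def test_linear_data_gives_identical_windows(self):
        years = np.arange(1900, 2001)
        sr = _rs(_series(years, lambda y: 5 + 0.02 * (y - 1900)))
        wt = window_trends(sr, windows=(10, 25, 50, "full"))
        assert wt["available"].all()
        spread = wt.groupby("region")["slope_per_decade"].agg(np.ptp)
        assert (spread < 1e-9).all()

    def test_full_window_equals_full_fit_slope(self):
        rng = np.random.default_rng(5)
        years = np.arange(1950, 2001)
        df = _series(years, lambda y: 3 + 0.01 * (y - 1950))
        df["sr"] += rng.normal(0, 0.2, len(df))
        sr = _rs(df)
        wt = window_trends(sr, windows=("full",)).set_index("region")
        full = decadal_slope(fit_trend_suite(
            sr, forms=("linear_interaction",)).fits["linear_interaction"])
        for _, row in full.iterrows():
            assert wt.loc[row["region"], "slope_per_decade"] == pytest.approx(
                row["slope_per_decade"], rel=1e-9)

    def test_recent_bump_flips_sign(self):
        years = np.arange(1900, 2001)
        sr = _rs(_series(
            years, lambda y: 20 - 0.03 * (y - 1900)
            + (0.5 * (y - 1990) if y > 1990 else 0.0)))
        wt = window_trends(sr, windows=(10, "full")).set_index(
            ["window", "region"])
        assert np.sign(wt.loc[(10, 1), "slope_per_decade"]) != \
            np.sign(wt.loc[("full", 1), "slope_per_decade"])

    def test_sparse_window_marked_unavailable(self):
        years = np.concatenate([np.arange(1900, 1990), [2000]])
        sr = _rs(_series(years, lambda y: 5 + 0.01 * (y - 1900)))
        wt = window_trends(sr, windows=(10, "full"))
        ten = wt[wt["window"] == 10]
        assert not ten["available"].any()
        assert (ten["direction"] == "unavailable").all()


class TestTraitTrends:
    def _stacked(self, slope_a, slope_b, noise_sd, rng):
        years = np.arange(1900, 2000)
        a = _series(years, lambda y: 6 + slope_a * (y - 1950), trait="A")
        b = _series(years, lambda y: 6 + slope_b * (y - 1950), trait="B")
        df = pd.concat([a, b], ignore_index=True)
        df["sr"] += rng.normal(0, noise_sd, len(df))
        return RichnessSeries(df, subset="trait", n_species=20)

    def test_identical_trends_rarely_flag_interaction(self):
        rng = np.random.default_rng(7)
        n_ns = 0
        reps = 40
        for _ in range(reps):
            res = fit_trait_trend(self._stacked(0.01, 0.01, 0.05, rng))
            n_ns += res.interaction_f_test["p"] >= 0.05
        assert n_ns >= 0.9 * reps

    def test_opposite_slopes_recovered(self):
        rng = np.random.default_rng(8)
        res = fit_trait_trend(self._stacked(0.01, -0.01, 0.02, rng))
        slopes = res.class_slopes.set_index(["trait", "region"])
        assert (slopes.loc["A"]["slope_per_decade"] > 0).all()
        assert (slopes.loc["B"]["slope_per_decade"] < 0).all()
        assert res.interaction_f_test["p"] < 0.05

    def test_single_class_rejected(self):
        rng = np.random.default_rng(9)
        df = self._stacked(0.01, 0.01, 0.05, rng).df
        df = df[df["trait"] == "A"]
        with pytest.raises(ValueError, match="trait"):
            fit_trait_trend(RichnessSeries(df, subset="t", n_species=10))
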