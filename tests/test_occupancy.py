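import numpy as np
import pytest
from scipy.special import expit, logit

from occutrends.dataprep import standardize_covariates
from occutrends.occupancy import (
    Design,
    OccupancyModelSpec,
    build_design,
    fit_occupancy,
    gof_parametric_bootstrap,
    negative_log_likelihood,
    occupancy_trajectory,
    select_model,
)
from occutrends.synth import SimConfig, SpeciesParams, generate_covariates, simulate_detection_history
from occutrends.validation import enumerate_likelihood


def _design(y, effort_z=None):
    """Constant-covariate design around a given detection matrix."""
    y = np.asarray(y, dtype=np.int8)
    x_det = np.zeros(y.shape) if effort_z is None else np.asarray(effort_z)
    return Design(y=y, x_dyn=None, x_det=x_det,
                  years=np.arange(1900, 1900 + y.shape[1]))


def _coeffs(gamma, eps, p):
    return np.array([logit(gamma), logit(eps), logit(p), 0.0])


SPEC = OccupancyModelSpec(dynamics="constant")


class TestNegativeLogLikelihood:
    def test_single_year_detection(self):
        # psi1 = 1 fixed, p = 0.5, y = (1): NLL = -ln 0.5
        nll = negative_log_likelihood(_coeffs(0.3, 0.2, 0.5), SPEC,
                                      _design([[1]]))
        np.testing.assert_allclose(nll, -np.log(0.5), atol=1e-12)

    def test_certain_detection_has_zero_nll(self):
        coeffs = np.array([0.0, 0.0, 40.0, 0.0])  # p ~ 1
        nll = negative_log_likelihood(coeffs, SPEC, _design([[1]]))
        assert nll == pytest.approx(0.0, abs=1e-12)

    def test_three_year_history_matches_enumeration(self):
        # y=(1,0,1), gamma=.3, eps=.2, p=.6: 4-term latent-state sum = 0.11376
        d = _design([[1, 0, 1]])
        nll = negative_log_likelihood(_coeffs(0.3, 0.2, 0.6), SPEC, d)
        np.testing.assert_allclose(np.exp(-nll), 0.11376, atol=1e-12)
        oracle = enumerate_likelihood(d.y, np.full((1, 3), 0.6),
                                      np.full((1, 3), 0.3),
                                      np.full((1, 3), 0.2), 1.0)
        np.testing.assert_allclose(np.exp(-nll), oracle, rtol=1e-12)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            T = int(rng.integers(1, 7))
            R = int(rng.integers(1, 3))
            p = rng.uniform(0.05, 0.95, (R, T))
            gamma = rng.uniform(0.05, 0.95, (R, T))
            eps = rng.uniform(0.05, 0.95, (R, T))
            psi1 = float(rng.uniform(0.1, 1.0))
            y = rng.integers(-1, 2, (R, T)).astype(np.int8)
            ref = enumerate_likelihood(y, p, gamma, eps, psi1)
            if ref <= 0:
                continue
            from occutrends._hmm import forward_nll

            fwd = np.exp(-forward_nll(np.ascontiguousarray(y), p, gamma, eps,
                                      psi1))
            np.testing.assert_allclose(fwd, ref, rtol=1e-10)

    def test_region_order_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(-1, 2, (4, 8)).astype(np.int8)
        eff = rng.normal(size=(4, 8))
        c = _coeffs(0.3, 0.2, 0.6)
        a = negative_log_likelihood(c, SPEC, _design(y, eff))
        perm = [2, 0, 3, 1]
        b = negative_log_likelihood(c, SPEC, _design(y[perm], eff[perm]))
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_rejects_bad_coefficients(self):
        with pytest.raises(ValueError, match="non-finite"):
            negative_log_likelihood([np.nan, 0, 0, 0], SPEC, _design([[1]]))
        with pytest.raises(ValueError, match="expected 4"):
            negative_log_likelihood([0.0, 0.0], SPEC, _design([[1]]))


@pytest.fixture(scope="module")
def fit():
    sp = SpeciesParams(name="sp", gamma_intercept=float(logit(0.4)),
                       eps_intercept=float(logit(0.3)),
                       p_intercept=0.3, p_effort=1.0)
    cfg = SimConfig(n_species=1, n_regions=40, n_years=50,
                    species_params=[sp], seed=17)
    data, _ = simulate_detection_history(cfg)
    cov = generate_covariates(cfg)
    std = standardize_covariates(cov, data.effort)
    design = build_design(SPEC, data, cov, std, "sp")
    return fit_occupancy(SPEC, design, n_restarts=3, seed=0), design


class TestFitAndSelect:
    def test_aic_identity_and_vcov_shape(self, fit):
        f, _ = fit
        assert f.aic == pytest.approx(2 * f.spec.n_params - 2 * f.loglik,
                                      abs=1e-9)
        assert f.vcov.shape == (4, 4)
        np.testing.assert_allclose(f.vcov, f.vcov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(f.vcov) > -1e-10)

    def test_estimates_near_truth(self, fit):
        f, _ = fit
        est = expit(f.coef[:2])
        for e, t, se_logit, prob in zip(est, (0.4, 0.3), f.se[:2], est):
            assert abs(e - t) < 4 * se_logit * prob * (1 - prob) + 1e-9

    def test_optimum_is_stationary(self, fit):
        f, design = fit
        refit = fit_occupancy(f.spec, design, n_restarts=1, seed=99)
        assert abs(refit.loglik - f.loglik) < 1e-6

    def test_fitted_probabilities_in_unit_interval(self, fit):
        f, _ = fit
        for arr in (f.gamma, f.eps, f.p):
            assert np.all((arr > 0) & (arr < 1))


class TestSelectModel:
    def _dummy(self, dynamics, aic, converged=True):
        spec = OccupancyModelSpec(dynamics=dynamics)
        k = spec.n_params
        return type("F", (), {"spec": spec, "aic": aic,
                              "loglik": (2 * k - aic) / 2,
                              "converged": converged})()

    def test_lowest_aic_wins(self):
        fits = [self._dummy(d, a) for d, a in
                zip(("constant", "year", "temperature", "forest"),
                    (100, 95, 102, 99))]
        best, table = select_model(fits)
        assert best.spec.dynamics == "year"
        assert table["aic"].min() == 95
        assert table.loc[table["dynamics"] == "year", "delta_aic"].iloc[0] == 0

    def test_tie_breaks_toward_fewer_parameters(self):
        fits = [self._dummy("constant", 100.0), self._dummy("year", 100.0)]
        best, _ = select_model(fits)
        assert best.spec.dynamics == "constant"

    def test_unconverged_fits_excluded(self):
        fits = [self._dummy("constant", 100), self._dummy("year", 90, False)]
        best, _ = select_model(fits)
        assert best.spec.dynamics == "constant"
        with pytest.raises(RuntimeError, match="no converged"):
            select_model([self._dummy("constant", 100, False)])


class TestTrajectories:
    def _fit_like(self, y, gamma, eps, p, psi1=1.0):
        y = np.asarray(y, dtype=np.int8)
        R, T = y.shape
        d = _design(y)
        spec = OccupancyModelSpec(dynamics="constant")
        from occutrends.occupancy import OccupancyFit

        return OccupancyFit(
            spec=spec, coef=_coeffs(gamma, eps, p), coef_names=spec.coef_names,
            vcov=None, loglik=0.0, aic=0.0, converged=True, message="",
            gamma=np.full((R, T), gamma), eps=np.full((R, T), eps),
            p=np.full((R, T), p), psi1=psi1, design=d)

    def test_projected_recursion_by_hand(self):
        # psi1=1, eps=.2, gamma=.25: psi2=.8, psi3=.8*.8+.2*.25=.69
        f = self._fit_like([[1, 0, 0]], gamma=0.25, eps=0.2, p=0.6)
        tr = occupancy_trajectory(f, mode="projected", burn_in_years=1)
        np.testing.assert_allclose(tr.prob[0], [1.0, 0.8, 0.69], atol=1e-12)
        assert tr.burn_in.tolist() == [True, False, False]

    def test_detection_implies_smoothed_one(self):
        f = self._fit_like([[1, 0, 1]], gamma=0.3, eps=0.2, p=0.6)
        tr = occupancy_trajectory(f, mode="smoothed")
        assert tr.prob[0, 0] == pytest.approx(1.0)
        assert tr.prob[0, 2] == pytest.approx(1.0)

    def test_smoothed_posterior_matches_enumeration(self):
        # y=(1,0): Pr(z2=1|y) = 0.192/0.312 = 8/13 by the two-term sum
        f = self._fit_like([[1, 0]], gamma=0.3, eps=0.2, p=0.6)
        tr = occupancy_trajectory(f, mode="smoothed")
        np.testing.assert_allclose(tr.prob[0, 1], 8.0 / 13.0, atol=1e-12)

    def test_smoothed_equals_projected_without_surveys(self):
        f = self._fit_like([[-1, -1, -1, -1]], gamma=0.3, eps=0.2, p=0.6,
                           psi1=0.7)
        sm = occupancy_trajectory(f, mode="smoothed").prob
        pr = occupancy_trajectory(f, mode="projected").prob
        np.testing.assert_allclose(sm, pr, atol=1e-12)

    def test_no_extinction_keeps_projection_at_one(self):
        f = self._fit_like([[1, -1, 0, 1]], gamma=0.42, eps=1e-15, p=0.6)
        tr = occupancy_trajectory(f, mode="projected")
        np.testing.assert_allclose(tr.prob, 1.0, atol=1e-12)

    def test_unknown_mode_rejected(self):
        f = self._fit_like([[1]], gamma=0.3, eps=0.2, p=0.6)
        with pytest.raises(ValueError, match="unknown trajectory mode"):
            occupancy_trajectory(f, mode="bogus")


class TestGof:
    def test_perfect_model_gives_p_one(self):
        from occutrends.occupancy import OccupancyFit

        y = np.ones((3, 10), dtype=np.int8)
        spec = OccupancyModelSpec(dynamics="constant")
        f = OccupancyFit(
            spec=spec, coef=np.array([0.0, -30.0, 30.0, 0.0]),
            coef_names=spec.coef_names, vcov=None, loglik=0.0, aic=0.0,
            converged=True, message="", gamma=np.full((3, 10), 0.5),
            eps=np.full((3, 10), 1e-13), p=np.full((3, 10), 1 - 1e-13),
            psi1=1.0, design=_design(y))
        g = gof_parametric_bootstrap(f, n_sim=19, seed=1, refit=False)
        assert g.statistic == pytest.approx(0.0, abs=1e-10)
        assert g.p_value == 1.0
        assert not g.poor_fit

    def test_deterministic_given_seed(self, fitted_study):
        f = next(iter(fitted_study["fits"].values()))
        a = gof_parametric_bootstrap(f, n_sim=19, seed=5)
        b = gof_parametric_bootstrap(f, n_sim=19, seed=5)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.sim_statistics, b.sim_statistics)

    def test_requires_at_least_one_simulation(self, fitted_study):
        f = next(iter(fitted_study["fits"].values()))
        with pytest.raises(ValueError, match="n_sim"):
            gof_parametric_bootstrap(f, n_sim=0)
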