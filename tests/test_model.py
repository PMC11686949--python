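"""Observation model, priors, linear predictors and the Laplace machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.spatial.distance import pdist, squareform
from scipy.stats import multivariate_normal, norm

from trophdyn.errors import ValidationError
from trophdyn.model import (
    FitData,
    ModelConfig,
    _Assembler,
    _obs_loglik_derivs,
    ar1_logdensity,
    delta_gamma_logpdf,
    joint_nll,
    laplace_marginal_nll,
    linear_predictors,
    matern_correlation,
    matern_covariance,
    poisson_link,
)
from trophdyn.synth import TruthParams, bird_sites, make_sites

from conftest import lean_config


class TestPoissonLink:
    def test_zero_density_limit(self):
        r1, r2 = poisson_link(0.0, 7.5, 1.0)
        assert r1 == 0.0
        assert r2 == pytest.approx(7.5)  # limit a*n/r1 -> 1

    def test_worked_example(self):
        r1, r2 = poisson_link(0.5, 10.0, 1.0)
        assert r1 == pytest.approx(1 - np.exp(-0.5), abs=1e-12)
        assert r2 == pytest.approx(0.5 * 10.0 / (1 - np.exp(-0.5)), abs=1e-9)
        assert r1 * r2 == pytest.approx(5.0, abs=1e-12)

    @given(
        n=st.floats(1e-8, 1e3), w=st.floats(1e-3, 1e4), a=st.floats(1e-2, 10.0)
    )
    @settings(max_examples=200, deadline=None)
    def test_identity_exact(self, n, w, a):
        r1, r2 = poisson_link(n, w, a)
        assert r1 * r2 == pytest.approx(a * n * w, rel=1e-12)
        assert 0 <= r1 <= 1  # r1 < 1 mathematically; saturates in floats

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            poisson_link(-0.1, 1.0, 1.0)


class TestDeltaGamma:
    def test_zero_atom(self):
        assert delta_gamma_logpdf(0.0, 0.3, 5.0, 0.8) == pytest.approx(
            np.log(0.7)
        )

    @pytest.mark.parametrize("r1,r2,sig", [(0.4, 25.0, 0.8), (0.9, 3.0, 1.5)])
    def test_density_integrates_to_one(self, r1, r2, sig):
        cont, _ = quad(
            lambda b: np.exp(delta_gamma_logpdf(b, r1, r2, sig)),
            1e-12, np.inf, limit=200,
        )
        total = (1 - r1) + cont
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_conditional_mean(self):
        from trophdyn.model import sample_delta_gamma

        rng = np.random.default_rng(0)
        draws = sample_delta_gamma(
            np.full(100_000, 0.6), np.full(100_000, 12.0), 0.8, rng
        )
        pos = draws[draws > 0]
        mc_se = pos.std() / np.sqrt(len(pos))
        assert abs(pos.mean() - 12.0) < 3 * mc_se

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValidationError):
            delta_gamma_logpdf(-1.0, 0.5, 1.0, 0.8)


class TestObservationDerivatives:
    def test_gradients_and_hessian_match_finite_differences(self):
        rng = np.random.default_rng(0)
        n = 60
        B = np.where(rng.uniform(size=n) < 0.4, 0.0, rng.gamma(2, 5, n))
        p1, p2 = rng.normal(0, 1, n), rng.normal(1, 0.5, n)
        loga, k = rng.normal(0, 0.2, n), rng.uniform(0.5, 4, n)
        _, g1, g2, h11, h12, h22 = _obs_loglik_derivs(B, p1, p2, loga, k)
        eps = 1e-6

        def f(a, b):
            return _obs_loglik_derivs(B, a, b, loga, k, want_derivs=False)[0]

        assert np.allclose(g1, (f(p1 + eps, p2) - f(p1 - eps, p2)) / (2 * eps),
                           atol=1e-6)
        assert np.allclose(g2, (f(p1, p2 + eps) - f(p1, p2 - eps)) / (2 * eps),
                           atol=1e-6)
        g1p = _obs_loglik_derivs(B, p1 + eps, p2, loga, k)[1]
        g1m = _obs_loglik_derivs(B, p1 - eps, p2, loga, k)[1]
        assert np.allclose(h11, (g1p - g1m) / (2 * eps), atol=1e-6)
        g1p2 = _obs_loglik_derivs(B, p1, p2 + eps, loga, k)[1]
        g1m2 = _obs_loglik_derivs(B, p1, p2 - eps, loga, k)[1]
        assert np.allclose(h12, (g1p2 - g1m2) / (2 * eps), atol=1e-6)
        g2p = _obs_loglik_derivs(B, p1, p2 + eps, loga, k)[2]
        g2m = _obs_loglik_derivs(B, p1, p2 - eps, loga, k)[2]
        assert np.allclose(h22, (g2p - g2m) / (2 * eps), atol=1e-6)


class TestMatern:
    def test_unit_at_zero_and_decreasing(self):
        d = np.linspace(0, 200, 50)
        c = matern_correlation(d, 60.0)
        assert c[0] == 1.0
        assert np.all(np.diff(c) < 0)

    def test_matches_sklearn_kernel(self):
        from sklearn.gaussian_process.kernels import Matern

        rng = np.random.default_rng(1)
        X = rng.uniform(0, 100, size=(5, 2))
        D = squareform(pdist(X))
        # sklearn uses sqrt(2 nu) d / l; our range parameter is l
        ours = matern_correlation(D, 37.0)
        theirs = Matern(length_scale=37.0, nu=1.0)(X)
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_covariance_validation(self):
        with pytest.raises(ValidationError):
            matern_covariance(np.array([[0.0, 1.0], [2.0, 0.0]]), 10.0)
        M = matern_covariance(squareform([5.0]), 10.0, jitter=1e-6)
        assert M[0, 0] == pytest.approx(1 + 1e-6)


class TestAR1Density:
    def test_rho_zero_reduces_to_independent_normals(self):
        x = np.array([0.3, -0.5, 1.1])
        got = ar1_logdensity(x, 0.2, 0.0, 0.7)
        want = norm.logpdf(x, 0.2, 0.7).sum()
        assert got == pytest.approx(want, abs=1e-12)

    def test_two_year_bivariate_closed_form(self):
        rho, sd = 0.6, 0.8
        marg = sd**2 / (1 - rho**2)
        cov = marg * np.array([[1.0, rho], [rho, 1.0]])
        x = np.array([0.4, -0.2])
        got = ar1_logdensity(x, 0.1, rho, sd)
        want = multivariate_normal.logpdf(x, mean=[0.1, 0.1], cov=cov)
        assert got == pytest.approx(want, abs=1e-12)

    def test_integrates_to_one(self):
        from scipy.integrate import dblquad

        rho, sd = 0.5, 0.6
        val, _ = dblquad(
            lambda y, x: np.exp(ar1_logdensity(np.array([x, y]), 0.0, rho, sd)),
            -6, 6, -6, 6,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_rho(self):
        with pytest.raises(ValidationError):
            ar1_logdensity(np.zeros(3), 0.0, 1.0, 0.5)


def _tiny_instance(seed=0, K=1, G=2, S=6, T=3):
    sites = make_sites(S, 1, "NB", 80.0, seed=seed)
    birds = bird_sites(sites)
    rng = np.random.default_rng(seed)
    years = list(range(2000, 2000 + T))
    rows, design_rows = [], []
    for s in birds["site_id"]:
        for t in years:
            for k in range(K):
                design_rows.append({
                    "site_id": s, "covariate": f"x{k}", "year": t,
                    "value": rng.normal(),
                })
            for g in range(G):
                rows.append({
                    "site_id": s, "year": t, "group_id": f"g{g}",
                    "biomass": 0.0 if rng.uniform() < 0.4 else rng.gamma(2, 4),
                })
    return (pd.DataFrame(rows), birds, pd.DataFrame(design_rows))


class TestLinearPredictors:
    def _zero_params(self, G, K):
        return {
            "beta1_mean": np.zeros(G), "ar1_rho": 0.0, "ar1_sd": 0.5,
            "beta2_mean": np.zeros(G), "gamma1": np.zeros(G * K),
            "gamma2": np.zeros(G * K),
            "L_omega1": np.zeros(2 * G - 1)[: len(range(G))],
            "range_km": 30.0, "sigma_m": np.full(G, 0.8),
        }

    def test_all_zero_params_give_unit_density_and_mass(self):
        biomass, birds, design = _tiny_instance()
        cfg = lean_config(include_census_effects=False)
        params = {
            "beta1_mean": np.zeros(2), "ar1_rho": 0.0, "ar1_sd": 0.5,
            "beta2_mean": np.zeros(2), "gamma1": np.zeros(2),
            "L_omega1": np.zeros(2), "range_km": 30.0,
            "sigma_m": np.full(2, 0.8),
        }
        p1, p2 = linear_predictors(biomass, birds, design, cfg, params, {})
        assert np.allclose(np.exp(p1), 1.0)
        assert np.allclose(np.exp(p2), 1.0)

    def test_unit_covariate_effect(self):
        biomass, birds, design = _tiny_instance()
        design = design.assign(value=1.0)
        cfg = lean_config(include_census_effects=False)
        params = {
            "beta1_mean": np.zeros(2), "ar1_rho": 0.0, "ar1_sd": 0.5,
            "beta2_mean": np.zeros(2), "gamma1": np.ones(2),
            "L_omega1": np.zeros(2), "range_km": 30.0,
            "sigma_m": np.full(2, 0.8),
        }
        p1, _ = linear_predictors(biomass, birds, design, cfg, params, {})
        assert np.allclose(np.exp(p1), np.e)

    def test_matches_bruteforce_sum_of_terms(self):
        rng = np.random.default_rng(3)
        biomass, birds, design = _tiny_instance(seed=3)
        cfg = ModelConfig(
            n_factors_spatial=1, n_factors_spatiotemporal=1,
            fields_on_predictor2=False, covariates_on_predictor2=False,
            year_effects_2="constant", include_census_effects=True,
            compute_se=False,
        )
        G, K, T = 2, 1, 3
        data = FitData(biomass, birds, design)
        params = {
            "beta1_mean": rng.normal(size=G), "ar1_rho": 0.4, "ar1_sd": 0.5,
            "beta2_mean": rng.normal(size=G), "gamma1": rng.normal(size=G * K),
            "L_omega1": rng.normal(size=G), "L_eps1": rng.normal(size=G),
            "range_km": 40.0, "sigma_m": np.full(G, 0.8),
            "census1": rng.normal(size=G), "census2": rng.normal(size=G),
        }
        S = data.S
        re = {
            "psi1": rng.normal(size=(S, 1)),
            "phi1": rng.normal(size=(S, T, 1)),
            "db1": rng.normal(size=(G, T)),
        }
        p1, p2 = linear_predictors(biomass, birds, design, cfg, params, re)
        Lom = params["L_omega1"].reshape(G, 1)
        Lep = params["L_eps1"].reshape(G, 1)
        gam = params["gamma1"].reshape(G, K)
        for i in range(data.n_rows):
            s, c, t = data.s_idx[i], data.c_idx[i], data.t_idx[i]
            expect = (
                params["beta1_mean"][c]
                + re["db1"][c, t]
                + gam[c] @ data.X[i]
                + Lom[c] @ re["psi1"][s]
                + Lep[c] @ re["phi1"][s, t]
            )
            if data.cens_idx[i] > 0:
                expect += params["census1"][c]
            assert p1[i] == pytest.approx(expect, abs=1e-12)
            expect2 = params["beta2_mean"][c]
            if data.cens_idx[i] > 0:
                expect2 += params["census2"][c]
            assert p2[i] == pytest.approx(expect2, abs=1e-12)


class TestJointNLL:
    def test_matches_hand_summed_terms(self):
        rng = np.random.default_rng(5)
        biomass, birds, design = _tiny_instance(seed=5)
        cfg = lean_config(include_census_effects=False)
        G, K = 2, 1
        data = FitData(biomass, birds, design)
        S, T = data.S, data.T
        params = {
            "beta1_mean": rng.normal(size=G), "ar1_rho": 0.3, "ar1_sd": 0.6,
            "beta2_mean": rng.normal(size=G) + 1.0,
            "gamma1": rng.normal(size=G * K),
            "L_omega1": rng.normal(size=G), "range_km": 40.0,
            "sigma_m": np.array([0.7, 1.1]),
        }
        re = {"psi1": rng.normal(size=(S, 1)), "db1": rng.normal(size=(G, T))}
        got = joint_nll(biomass, birds, design, cfg, params, re)

        p1, p2 = linear_predictors(biomass, birds, design, cfg, params, re)
        r1, r2 = (
            1 - np.exp(-data.area * np.exp(p1)),
            data.area * np.exp(p1) * np.exp(p2) / (1 - np.exp(-data.area * np.exp(p1))),
        )
        sig = params["sigma_m"][data.c_idx]
        obs_ll = delta_gamma_logpdf(data.B, r1, r2, sig).sum()
        prior_ll = sum(
            ar1_logdensity(re["db1"][c], 0.0, 0.3, 0.6) for c in range(G)
        )
        C = matern_correlation(
            squareform(pdist(data.coords)), 40.0
        ) + cfg.jitter * np.eye(S)
        prior_ll += multivariate_normal.logpdf(
            re["psi1"][:, 0], mean=np.zeros(S), cov=C
        )
        assert got == pytest.approx(-(obs_ll + prior_ll), abs=1e-8)

    def test_joint_gradient_and_hessian_consistent(self):
        rng = np.random.default_rng(6)
        biomass, birds, design = _tiny_instance(seed=6)
        cfg = lean_config(include_census_effects=False)
        data = FitData(biomass, birds, design)
        asm = _Assembler(data, cfg)
        nat = asm.initial_natural()
        prep = asm.prepare(nat)
        u = 0.3 * rng.standard_normal(asm.n_u)
        f, g = asm.joint_fg(prep, u)
        H = asm.joint_hess(prep, u)
        eps = 1e-6
        for j in rng.choice(asm.n_u, size=6, replace=False):
            e = np.zeros(asm.n_u)
            e[j] = eps
            fp, gp = asm.joint_fg(prep, u + e)
            fm, gm = asm.joint_fg(prep, u - e)
            assert g[j] == pytest.approx((fp - fm) / (2 * eps), abs=1e-5)
            assert np.allclose(H[:, j], (gp - gm) / (2 * eps), atol=1e-5)


class TestLaplace:
    def test_zero_variance_limit_equals_fixed_effect_nll(self):
        biomass, birds, design = _tiny_instance(seed=7)
        cfg = lean_config(
            n_factors_spatial=0, include_census_effects=False,
            estimate_ar1=False,
        )
        params = {
            "beta1_mean": np.array([0.1, -0.2]), "ar1_sd": 1e-8,
            "beta2_mean": np.array([1.0, 1.2]), "gamma1": np.zeros(2),
            "sigma_m": np.array([0.8, 0.8]),
        }
        lap, modes = laplace_marginal_nll(biomass, birds, design, cfg, params)
        fixed = joint_nll(
            biomass, birds, design,
            lean_config(n_factors_spatial=0, include_census_effects=False,
                        estimate_ar1=False),
            {**params, "ar1_sd": 1.0},  # prior term dropped below
            {"db1": np.zeros((2, 3))},
        )
        # subtract the (zero-deviation) AR1 prior contribution analytically
        data = FitData(biomass, birds, design)
        prior = -sum(
            ar1_logdensity(np.zeros(data.T), 0.0, 0.0, 1.0) for _ in range(2)
        )
        assert lap == pytest.approx(fixed - prior, abs=1e-6)
        assert np.allclose(modes["db1"], 0.0, atol=1e-6)

    def test_matches_adaptive_quadrature_on_shared_intercept_toy(self):
        # single Gaussian random intercept shared by 200 observations
        rng = np.random.default_rng(3)
        n = 200
        sites = make_sites(n, 1, "NB", 100.0, seed=3)
        birds = bird_sites(sites).copy()
        birds["area_offset"] = 1.0
        mu1, mu2, sig, sd1, v_true = 0.2, 1.0, 0.6, 0.5, 0.3
        nr = np.exp(mu1 + v_true)
        r1 = -np.expm1(-nr)
        occ = rng.uniform(size=n) < r1
        k = 1 / sig**2
        B = np.zeros(n)
        B[occ] = rng.gamma(k, (nr * np.exp(mu2) / r1) * sig**2, occ.sum())
        biomass = pd.DataFrame({
            "site_id": birds["site_id"], "year": 2000,
            "group_id": "G1", "biomass": B,
        })
        cfg = lean_config(
            n_factors_spatial=0, include_census_effects=False,
            estimate_ar1=False,
        )
        params = {
            "beta1_mean": np.array([mu1]), "ar1_sd": sd1,
            "beta2_mean": np.array([mu2]), "sigma_m": np.array([sig]),
        }
        lap, modes = laplace_marginal_nll(biomass, birds, None, cfg, params)

        loga = np.zeros(n)
        kk = np.full(n, k)

        def joint_v(v):
            ll = _obs_loglik_derivs(
                B, np.full(n, mu1 + v), np.full(n, mu2), loga, kk,
                want_derivs=False,
            )[0]
            return ll.sum() - 0.5 * (v**2 / sd1**2 + np.log(2 * np.pi * sd1**2))

        c = joint_v(float(modes["db1"][0]))
        val, _ = quad(lambda v: np.exp(joint_v(v) - c), -5, 5, limit=200)
        quad_nll = -(np.log(val) + c)
        assert abs(lap - quad_nll) < 1e-3


class TestFitContracts:
    def test_refit_from_optimum_is_a_fixed_point(self, small_scenario, small_fit):
        biomass, birds, design, _ = small_scenario
        from trophdyn.model import fit_jdsdm

        refit = fit_jdsdm(
            biomass, birds, design,
            lean_config(max_outer_iter=5), start=small_fit.params,
        )
        assert refit.marginal_nll == pytest.approx(
            small_fit.marginal_nll, abs=1e-6
        )

    def test_row_permutation_invariance(self, small_scenario, small_fit):
        biomass, birds, design, _ = small_scenario
        shuffled = biomass.sample(frac=1.0, random_state=0).reset_index(drop=True)
        val, _ = laplace_marginal_nll(
            shuffled, birds, design, small_fit.config, small_fit.params
        )
        assert val == pytest.approx(small_fit.marginal_nll, abs=1e-8)

    def test_convergence_flag_honours_gradient(self, small_fit):
        assert small_fit.converged
        assert small_fit.grad_norm <= small_fit.config.outer_gtol

    def test_full_feature_fit_smoke(self):
        # every structural term on at once, small instance, capped iterations
        from trophdyn.model import fit_jdsdm

        sites = make_sites(14, 1, "MB", 150.0, seed=9)
        birds = bird_sites(sites)
        truth = TruthParams(
            intercept_mean=[0.0, 0.3], ar1_rho=0.4, ar1_sd=0.3,
            covariate_effects=np.full((2, 1), 0.3),
            spatial_loadings=[[0.4], [0.3]],
            spatiotemporal_loadings=[[0.3], [0.2]],
            overdispersion_sd=0.2, matern_range_km=50.0,
        )
        from trophdyn.synth import (
            simulate_anomaly_covariates,
            simulate_latent_fields,
            simulate_observations,
        )

        years = list(range(2000, 2005))
        design = simulate_anomaly_covariates(birds, years, seed=10)
        fields = simulate_latent_fields(sites, 5, truth, seed=11)
        biomass = simulate_observations(
            sites, fields, design, truth, seed=12, years_labels=years
        )
        cfg = ModelConfig(
            n_factors_spatial=1, n_factors_spatiotemporal=1,
            fields_on_predictor2=True, covariates_on_predictor2=True,
            year_effects_2="iid", include_overdispersion=True,
            compute_se=False, max_outer_iter=25, seed=0,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_jdsdm(biomass, birds, design, cfg)
        assert np.isfinite(fit.marginal_nll)
        assert set(fit.modes) >= {"psi1", "psi2", "phi1", "phi2", "db1", "db2",
                                  "eta1", "eta2"}
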