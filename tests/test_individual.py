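"""Individual-level estimators: OLS, 2SLS, conditional F, scaling,
selection weights."""

import numpy as np
import pandas as pd
import pytest

import edumr
from edumr import (
    SimParams,
    conditional_f,
    ols_estimate,
    sd_scale,
    selection_weights,
    simulate_cohort,
    tsls_multivariable,
    tsls_univariable,
)
def residualise(v, W):
    Wi = np.column_stack([np.ones(len(W)), W])
    return v - Wi @ np.linalg.lstsq(Wi, v, rcond=None)[0]


@pytest.fixture(scope="module")
def iv_instance():
    """Small random IV problem with two covariates."""
    rng = np.random.default_rng(7)
    n = 200
    W = rng.standard_normal((n, 2))
    z = rng.standard_normal(n)
    u = rng.standard_normal(n)
    x = 0.8 * z + W @ [0.3, -0.2] + 0.5 * u + rng.standard_normal(n)
    y = -0.4 * x + W @ [0.1, 0.2] + u + rng.standard_normal(n)
    return y, x, z, W


class TestOls:
    def test_weight_invariance(self, rng):
        n = 300
        X = rng.standard_normal((n, 2))
        W = rng.standard_normal((n, 3))
        y = (rng.random(n) < 0.3).astype(float)
        a = ols_estimate(y, X, W)
        b = ols_estimate(y, X, W, weights=np.full(n, 7.0))
        for ea, eb in zip(a, b):
            assert np.isclose(ea.effect, eb.effect)
            assert np.isclose(ea.se, eb.se)

    def test_degenerate_outcome_flagged(self, rng):
        n = 100
        X = rng.standard_normal((n, 1))
        W = rng.standard_normal((n, 2))
        (est,) = ols_estimate(np.zeros(n), X, W)
        assert est.effect == 0
        assert est.degenerate

    def test_collinear_design_rejected(self, rng):
        n = 100
        X = rng.standard_normal((n, 1))
        with pytest.raises(ValueError, match="rank deficient"):
            ols_estimate(rng.random(n), X, np.column_stack([X, X]))


class TestTslsUnivariable:
    def test_closed_form_covariance_ratio(self, iv_instance):
        """Just-identified IV equals cov(z~,y~)/cov(z~,x~) after
        residualising the covariates (Frisch–Waugh)."""
        y, x, z, W = iv_instance
        est = tsls_univariable(y, x, z, W)
        zt, yt, xt = (residualise(v, W) for v in (z, y, x))
        closed = np.dot(zt, yt) / np.dot(zt, xt)
        np.testing.assert_allclose(est.effect, closed, rtol=1e-10)

    def test_matches_statsmodels_iv2sls(self, iv_instance):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        y, x, z, W = iv_instance
        est = tsls_univariable(y, x, z, W)
        exog = np.column_stack([np.ones(len(y)), W, x])
        instr = np.column_stack([np.ones(len(y)), W, z])
        fit = IV2SLS(y, exog, instrument=instr).fit()
        np.testing.assert_allclose(est.effect, fit.params[-1], rtol=1e-10)

    def test_perfect_instrument_equals_ols(self, rng):
        n = 500
        W = rng.standard_normal((n, 2))
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.4 + 0.1 * np.tanh(x)).astype(float)
        iv = tsls_univariable(y, x, x, W)
        (ols,) = ols_estimate(y, x, W)
        np.testing.assert_allclose(iv.effect, ols.effect, rtol=1e-10)

    def test_weak_instrument_warns(self, rng):
        n = 500
        W = rng.standard_normal((n, 1))
        z = rng.standard_normal(n)
        x = 0.01 * z + rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        with pytest.warns(UserWarning, match="weak instrument"):
            tsls_univariable(y, x, z, W)

    def test_total_effect_under_mediation(self):
        """Education upstream of cognition: univariable education MR
        targets beta1 + alpha_E * beta2, not beta1."""
        p = SimParams(
            n_individuals=60_000, n_snps_edu=20, n_snps_cog=10,
            beta1=-0.02, beta2=0.08, alpha_E=0.5, alpha_CA=0.0,
            r2_edu=0.02, r2_cog=0.02, seed=31,
        )
        cohort, panel = simulate_cohort(p)
        score = edumr.compute_prs(cohort.dosages, panel, "edu")
        covs = edumr.build_covariates(cohort.covariates, 0)
        est = tsls_univariable(
            cohort.smoke_ever.astype(float), cohort.edu_years, score, covs
        )
        total = p.beta1 + p.alpha_E * p.beta2  # = -0.006
        assert abs(est.effect - total) < 3 * est.se
        assert abs(est.effect - p.beta1) > 3 * est.se


class TestTslsMultivariable:
    def test_projection_closed_form(self, rng):
        """Two-endogenous-regressor IV equals the generic projection
        formula (Xhat'X)^-1 Xhat'y."""
        n = 300
        W = rng.standard_normal((n, 2))
        Z = rng.standard_normal((n, 2))
        X = Z @ rng.uniform(0.5, 1.0, (2, 2)) + rng.standard_normal((n, 2))
        y = X @ [0.3, -0.2] + rng.standard_normal(n)
        ests = tsls_multivariable(y, X, Z, W)
        Wi = np.column_stack([np.ones(n), W])
        Xf = np.column_stack([Wi, X])
        Zf = np.column_stack([Wi, Z])
        Xhat = Zf @ np.linalg.lstsq(Zf, Xf, rcond=None)[0]
        beta = np.linalg.solve(Xhat.T @ Xf, Xhat.T @ y)
        np.testing.assert_allclose(
            [e.effect for e in ests], beta[-2:], rtol=1e-9
        )

    def test_confounded_ols_biased_tsls_not(self):
        """The pipeline's central property: confounding biases OLS but
        not the score-instrumented 2SLS."""
        p = SimParams(
            n_individuals=40_000, n_snps_edu=20, n_snps_cog=10,
            beta1=-0.04, beta2=0.0, alpha_CA=0.0,
            confounder_effects=(1.0, 0.3, 0.08), seed=23,
        )
        cohort, panel = simulate_cohort(p)
        covs = edumr.build_covariates(cohort.covariates, 0)
        X = np.column_stack([cohort.edu_years, cohort.cog_score])
        Z = np.column_stack(
            [
                edumr.compute_prs(cohort.dosages, panel, "edu"),
                edumr.compute_prs(cohort.dosages, panel, "cog"),
            ]
        )
        y = cohort.smoke_ever.astype(float)
        ols = ols_estimate(y, X, covs)
        iv = tsls_multivariable(y, X, Z, covs)
        assert abs(ols[0].effect - p.beta1) > 3 * ols[0].se  # biased
        assert abs(iv[0].effect - p.beta1) < 3 * iv[0].se    # consistent

    def test_null_second_exposure(self, rng):
        n = 5000
        W = rng.standard_normal((n, 2))
        Z = rng.standard_normal((n, 2))
        x1 = Z[:, 0] + rng.standard_normal(n)
        x2 = Z[:, 1] + rng.standard_normal(n)
        y = 0.5 * x1 + rng.standard_normal(n)  # x2 truly null
        est = tsls_multivariable(y, np.column_stack([x1, x2]), Z, W)[1]
        assert abs(est.effect) < 3 * est.se

    def test_collinear_scores_rejected(self, rng):
        n = 1000
        W = rng.standard_normal((n, 1))
        z = rng.standard_normal(n)
        Z = np.column_stack([z, z * (1 + 1e-8)])
        X = rng.standard_normal((n, 2))
        with pytest.raises(ValueError, match="collinear"):
            tsls_multivariable(rng.random(n), X, Z, W)


class TestConditionalF:
    def test_single_exposure_reduces_to_first_stage_f(self, iv_instance):
        y, x, z, W = iv_instance
        est = tsls_univariable(y, x, z, W)
        cf = conditional_f(x[:, None], z[:, None], W)
        np.testing.assert_allclose(cf[0], est.f_stat, rtol=1e-9)

    def test_independent_instruments_limit(self, rng):
        """Orthogonal scores, each driving its own exposure: conditional F
        stays close to the unconditional F."""
        n = 20_000
        W = rng.standard_normal((n, 2))
        Z = rng.standard_normal((n, 2))
        X = np.column_stack(
            [
                0.3 * Z[:, 0] + rng.standard_normal(n),
                0.3 * Z[:, 1] + rng.standard_normal(n),
            ]
        )
        cf = conditional_f(X, Z, W)
        from edumr.individual import _first_stage_f

        for j in range(2):
            # with orthogonal scores the conditional F approaches the F of
            # the exposure's own instrument alone
            f_own = _first_stage_f(X[:, j], Z[:, j], W)
            assert abs(cf[j] / f_own - 1) < 0.15

    def test_collinearity_drives_conditional_f_down(self, rng):
        """As the two scores become collinear, conditional F collapses
        while the unconditional F is unchanged — the F >> conditional-F
        pattern of strongly correlated exposures."""
        from edumr.individual import _first_stage_f

        n = 5000
        W = rng.standard_normal((n, 1))
        z1 = rng.standard_normal(n)
        zi = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        cond_fs, fs = [], []
        for rho in (0.0, 0.5, 0.9, 0.99, 0.999):
            z2 = rho * z1 + np.sqrt(1 - rho**2) * zi
            X = np.column_stack([0.5 * z1 + e1, 0.5 * z2 + e2])
            Z = np.column_stack([z1, z2])
            cond_fs.append(conditional_f(X, Z, W)[0])
            fs.append(_first_stage_f(X[:, 0], Z, W))
        assert all(a > b for a, b in zip(cond_fs, cond_fs[1:]))  # monotone
        assert cond_fs[-1] < 0.05 * fs[-1]  # collapse despite large F
        assert min(fs) > 100


class TestScalingAndWeights:
    @pytest.mark.parametrize(
        "effect,sd,per_sd,pct",
        [
            (-0.026, 2.4, -0.0624, 6.2),
            (-0.041, 2.4, -0.0984, 9.8),
            (-0.091, 2.4, -0.2184, 21.8),
            (0.0, 2.4, 0.0, 0.0),
        ],
    )
    def test_sd_scale(self, effect, sd, per_sd, pct):
        got_per_sd, got_pct = sd_scale(effect, sd)
        np.testing.assert_allclose(got_per_sd, per_sd, atol=1e-12)
        assert got_pct == pct

    def test_selection_weights_identities(self):
        strata = ["left_school_before_16", "intermediate", "degree"]
        sample = pd.Series([0.1, 0.5, 0.4], index=strata)
        pop = pd.Series([0.2, 0.5, 0.3], index=strata)
        w = selection_weights(sample, pop)
        np.testing.assert_allclose(w["left_school_before_16"], 2.0)
        np.testing.assert_allclose(w["intermediate"], 1.0)
        # reweighted sample frequencies reproduce the population
        np.testing.assert_allclose(sample * w, pop)
        # identical distributions give unit weights
        np.testing.assert_allclose(selection_weights(pop, pop), 1.0)

    def test_empty_stratum_errors(self):
        with pytest.raises(ValueError, match="empty"):
            selection_weights({"a": 0.0, "b": 1.0}, {"a": 0.3, "b": 0.7})

    def test_weighted_estimates_match_unweighted_under_uniform_selection(
        self, small_cohort
    ):
        cohort, panel = small_cohort
        covs = edumr.build_covariates(cohort.covariates, 2)
        score = edumr.compute_prs(cohort.dosages, panel, "edu")
        y = cohort.smoke_ever.astype(float)
        a = tsls_univariable(y, cohort.edu_years, score, covs)
        b = tsls_univariable(
            y, cohort.edu_years, score, covs, weights=np.full(cohort.n, 3.0)
        )
        np.testing.assert_allclose(a.effect, b.effect, rtol=1e-8)

    def test_covariate_affine_invariance(self, iv_instance):
        y, x, z, W = iv_instance
        a = tsls_univariable(y, x, z, W)
        b = tsls_univariable(y, x, z, W * 3.5 + 11.0)
        np.testing.assert_allclose(a.effect, b.effect, rtol=1e-9)
        np.testing.assert_allclose(a.se, b.se, rtol=1e-8)
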