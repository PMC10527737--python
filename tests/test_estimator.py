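import numpy as np
import pytest

from cenplam import (
    CensoredDataset,
    PLAMRegressor,
    backfit,
    beta_bias,
    beta_variance,
    center_smoother,
    estimate_variance,
    fit_noniterative,
    llr_smoother,
)

FIXED_H = [0.25, 0.8]


class TestBackfitting:
    def test_uncensored_q1_matches_two_stage_closed_form(self):
        # classical partially linear estimator: beta = (X'Xt)^{-1} X'Zt with
        # Xt = (I-S)X, Zt = (I-S)Zc, then f = S(Zc - X beta)
        rng = np.random.default_rng(0)
        n = 40
        t = np.sort(rng.uniform(0, 1, n))
        X = rng.standard_normal((n, 2))
        z = X @ [1.0, -0.5] + np.sin(2 * np.pi * t) + rng.normal(0, 0.3, n)
        ds = CensoredDataset(z=z, delta=np.ones(n, dtype=int), X=X,
                             T=t.reshape(-1, 1))
        fit = backfit(ds, "st", bandwidths=[0.15], tol=1e-12, max_iter=1000)
        S = center_smoother(llr_smoother(t, 0.15)).S
        zc = z - z.mean()
        Xc = X - X.mean(axis=0)  # model works on covariates scaled to zero
        Xt = Xc - S @ Xc
        beta = np.linalg.solve(Xc.T @ Xt, Xc.T @ (zc - S @ zc))
        f = S @ (zc - Xc @ beta)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-6)
        np.testing.assert_allclose(fit.components[:, 0], f, atol=1e-6)

    def test_noiseless_affine_component_reproduced_exactly(self):
        n = 25
        t = np.linspace(0, 1, n)
        z = 2.0 + 3.0 * t
        ds = CensoredDataset(z=z, delta=np.ones(n, dtype=int),
                             X=np.zeros((n, 1)), T=t.reshape(-1, 1))
        est = PLAMRegressor(n_parametric=0, method="st", bandwidths=[0.3],
                            tol=1e-12, max_iter=200)
        est.fit(t.reshape(-1, 1), z)
        assert est.intercept_ == pytest.approx(z.mean())
        np.testing.assert_allclose(
            est.components_[:, 0], z - z.mean(), atol=1e-8
        )

    @pytest.mark.parametrize("method", ["st", "kmw", "knni"])
    def test_matches_noniterative_solution(self, method, censored_ds):
        data, _ = censored_ds
        bf = backfit(data, method, bandwidths=FIXED_H, tol=1e-11,
                     max_iter=2000, k=3)
        ni = fit_noniterative(data, method, bandwidths=FIXED_H, k=3)
        np.testing.assert_allclose(bf.fitted_values, ni.fitted_values,
                                   atol=1e-6)
        np.testing.assert_allclose(bf.beta, ni.beta, atol=1e-6)
        np.testing.assert_allclose(bf.components, ni.components, atol=1e-6)

    @pytest.mark.parametrize("method", ["st", "kmw", "knni"])
    def test_fitted_values_decompose_and_components_are_centered(
        self, method, censored_ds
    ):
        data, _ = censored_ds
        fit = backfit(data, method, bandwidths=FIXED_H, tol=1e-10,
                      max_iter=2000, k=3)
        assert np.abs(fit.components.mean(axis=0)).max() < 1e-8
        recon = fit.beta0 + data.X @ fit.beta + fit.components.sum(axis=1)
        np.testing.assert_allclose(fit.fitted_values, recon, atol=1e-8)
        assert fit.sigma2 >= 0 and fit.df > 0
        assert fit.converged

    def test_hat_matrix_reproduces_fitted_values(self, censored_ds):
        data, _ = censored_ds
        fit = fit_noniterative(data, "kmw", bandwidths=FIXED_H)
        center = fit.extras["response_center"]
        zc = fit.working_response - center
        np.testing.assert_allclose(fit.hat @ zc + center,
                                   fit.fitted_values, atol=1e-10)

    def test_no_censoring_reduces_all_methods_to_common_fit(self,
                                                            uncensored_ds):
        fits = {
            m: backfit(uncensored_ds, m, bandwidths=FIXED_H, tol=1e-10,
                       max_iter=1000)
            for m in ("st", "kmw", "knni")
        }
        for m in ("kmw", "knni"):
            np.testing.assert_allclose(fits[m].beta, fits["st"].beta,
                                       atol=1e-8)
            np.testing.assert_allclose(fits[m].fitted_values,
                                       fits["st"].fitted_values, atol=1e-8)

    def test_identifiability_under_component_shift(self):
        # adding a constant to a true component and removing it from the
        # intercept must leave the fitted values unchanged
        rng = np.random.default_rng(11)
        n = 35
        t = np.sort(rng.uniform(0, 1, n))
        X = rng.standard_normal((n, 1))
        base = X[:, 0] + np.sin(2 * np.pi * t)
        for shift in (0.0, 5.0):
            z = base + shift  # constant absorbed by the intercept
            ds = CensoredDataset(z=z, delta=np.ones(n, dtype=int), X=X,
                                 T=t.reshape(-1, 1))
            fit = backfit(ds, "st", bandwidths=[0.2], tol=1e-12,
                          max_iter=1000)
            if shift == 0.0:
                ref = fit
            else:
                np.testing.assert_allclose(
                    fit.fitted_values - shift, ref.fitted_values, atol=1e-8
                )
                np.testing.assert_allclose(fit.components, ref.components,
                                           atol=1e-8)

    def test_nonconvergence_is_flagged_not_raised(self, censored_ds):
        data, _ = censored_ds
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = backfit(data, "kmw", bandwidths=FIXED_H, tol=1e-14,
                          max_iter=2)
        assert not fit.converged
        assert fit.iterations == 2

    def test_coefficient_recovery_without_censoring(self):
        # small replication study at n=200: the mean estimate must sit
        # within Monte-Carlo error of the generating coefficients
        from cenplam import ScenarioConfig, run_scenario

        cfg = ScenarioConfig(n=200, cl=0.0, reps=40, seed=77,
                             methods=("kmw",))
        res = run_scenario(cfg)
        bh = res.beta_hats["kmw"]
        se = bh.std(axis=0, ddof=1) / np.sqrt(len(bh))
        assert np.all(np.abs(bh.mean(axis=0) - [1.0, -0.5]) < 3 * se)


class TestNonIterative:
    def test_q1_additive_smoother_is_single_centered_smoother(self):
        rng = np.random.default_rng(5)
        n = 25
        t = np.sort(rng.uniform(0, 1, n))
        X = rng.standard_normal((n, 1))
        z = X[:, 0] + t**2 + rng.normal(0, 0.2, n)
        ds = CensoredDataset(z=z, delta=np.ones(n, dtype=int), X=X,
                             T=t.reshape(-1, 1))
        fit = fit_noniterative(ds, "st", bandwidths=[0.3])
        Sc = center_smoother(llr_smoother(t, 0.3)).S
        np.testing.assert_allclose(fit.extras["S_A"], Sc, atol=1e-12)

    def test_identity_weights_reduce_weighted_to_unweighted_formula(self,
                                                                    uncensored_ds):
        st_fit = fit_noniterative(uncensored_ds, "st", bandwidths=FIXED_H)
        kmw_fit = fit_noniterative(uncensored_ds, "kmw", bandwidths=FIXED_H)
        # without censoring the KM weights are 1/n: same normal equations
        np.testing.assert_allclose(st_fit.beta, kmw_fit.beta, atol=1e-10)

    def test_size_guard(self):
        rng = np.random.default_rng(1)
        n = 350
        ds = CensoredDataset(z=rng.normal(size=n),
                             delta=np.ones(n, dtype=int),
                             X=rng.standard_normal((n, 1)),
                             T=rng.uniform(0, 1, (n, 1)))
        with pytest.raises(ValueError, match="guard"):
            fit_noniterative(ds, "st", bandwidths=[0.3])


class TestDiagnostics:
    def test_variance_estimate_limits(self):
        z = np.array([1.0, -2.0, 0.5, 1.5, -1.0])
        H = np.eye(5)
        with pytest.raises(ValueError):
            estimate_variance(z, H)  # df = 0
        assert estimate_variance(z, np.zeros((5, 5))) == pytest.approx(
            np.mean(z**2)
        )
        P = np.outer(np.ones(5), np.ones(5)) / 5
        assert estimate_variance(P @ z + (z - P @ z), np.eye(5) * 0.0) >= 0

    def test_variance_recovery_from_simulation(self):
        from cenplam import ScenarioConfig, generate_censored_dataset

        s2 = []
        for r in range(25):
            data, _ = generate_censored_dataset(
                ScenarioConfig(n=200, cl=0.0, seed=900 + r), seed=900 + r
            )
            s2.append(backfit(data, "kmw").sigma2)
        assert abs(np.mean(s2) - 0.5) < 0.15 * 0.5

    def test_bias_zero_for_zero_truth_and_small_for_affine(self,
                                                           censored_ds):
        data, _ = censored_ds
        fit = fit_noniterative(data, "kmw", bandwidths=FIXED_H)
        zero = beta_bias(fit, np.zeros_like(fit.components), data.X)
        np.testing.assert_allclose(zero, 0.0, atol=1e-12)
        affine = np.column_stack([
            data.T[:, 0] - data.T[:, 0].mean(),
            2.0 * (data.T[:, 1] - data.T[:, 1].mean()),
        ])
        small = beta_bias(fit, affine, data.X)
        assert np.abs(small).max() < 1e-6

    def test_bias_matches_direct_matrix_product(self, censored_ds):
        data, f_true = censored_ds
        fit = fit_noniterative(data, "st", bandwidths=FIXED_H)
        S_A = fit.extras["S_A"]
        smo = fit.extras["component_smoothers"]
        f_tilde = sum(f_true[:, j] - smo[j] @ f_true[:, j] for j in range(2))
        Xt = data.X - S_A @ data.X
        expected = np.linalg.solve(data.X.T @ Xt, data.X.T @ f_tilde)
        np.testing.assert_allclose(beta_bias(fit, f_true, data.X), expected,
                                   atol=1e-10)

    def test_variance_limits_and_brute_force(self, censored_ds):
        data, _ = censored_ds
        fit = fit_noniterative(data, "st", bandwidths=FIXED_H)
        V = beta_variance(fit, data.X)
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) >= -1e-12)
        # brute force the sandwich
        n = data.n
        S_A = fit.extras["S_A"]
        A = data.X.T @ (np.eye(n) - S_A)
        G = data.X.T @ (data.X - S_A @ data.X)
        Gi = np.linalg.inv(G)
        np.testing.assert_allclose(V, fit.sigma2 * Gi @ A @ A.T @ Gi.T,
                                   atol=1e-10)
        # sigma2 = 0 gives the zero matrix
        fit.sigma2 = 0.0
        np.testing.assert_allclose(beta_variance(fit, data.X), 0.0)

    def test_ols_covariance_limit_without_smoothing(self):
        rng = np.random.default_rng(2)
        n = 20
        X = rng.standard_normal((n, 2))
        from cenplam.estimator import PLAMFit

        fit = PLAMFit(
            beta0=0.0, beta=np.zeros(2), components=np.zeros((n, 0)),
            bandwidths=np.zeros(0), hat=np.zeros((n, n)), sigma2=2.5,
            df=float(n), method="st", iterations=0, converged=True,
            fitted_values=np.zeros(n), working_response=np.zeros(n),
            extras={"S_A": np.zeros((n, n)), "component_smoothers": []},
        )
        V = beta_variance(fit, X)
        np.testing.assert_allclose(V, 2.5 * np.linalg.inv(X.T @ X),
                                   atol=1e-10)


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, censored_ds):
        data, _ = censored_ds
        est = PLAMRegressor(n_parametric=2, method="kmw", solver="direct",
                            bandwidths=FIXED_H)
        Xfull = np.hstack([data.X, data.T])
        est.fit(Xfull, data.z, data.delta)
        np.testing.assert_allclose(est.predict(Xfull), est.fitted_values_,
                                   atol=1e-8)

    def test_parametric_only_model_is_linear_predictor(self):
        rng = np.random.default_rng(4)
        n = 30
        X = rng.standard_normal((n, 2))
        z = X @ [2.0, 1.0] + 0.5
        est = PLAMRegressor(n_parametric=2, method="st")
        est.fit(X, z)
        np.testing.assert_allclose(
            est.predict(X), est.intercept_ + X @ est.coef_, atol=1e-10
        )
        np.testing.assert_allclose(est.coef_, [2.0, 1.0], atol=1e-8)

    def test_midpoint_of_affine_component_interpolates(self):
        n = 21
        t = np.linspace(0, 1, n)
        z = 1.0 + 2.0 * t
        est = PLAMRegressor(n_parametric=0, method="st", solver="direct",
                            bandwidths=[0.3])
        est.fit(t.reshape(-1, 1), z)
        mid = (t[3] + t[4]) / 2
        pred = est.predict(np.array([[mid]]))
        assert pred[0] == pytest.approx(1.0 + 2.0 * mid, abs=1e-8)

    def test_extrapolation_warns(self):
        t = np.linspace(0, 1, 15)
        est = PLAMRegressor(n_parametric=0, method="st", bandwidths=[0.3])
        est.fit(t.reshape(-1, 1), np.sin(t))
        with pytest.warns(RuntimeWarning, match="extrapolation"):
            est.predict(np.array([[1.5]]))


class TestSklearnProtocol:
    def test_get_set_params_roundtrip(self):
        est = PLAMRegressor(n_parametric=2, method="knni", k=4)
        params = est.get_params()
        est2 = PLAMRegressor(**params)
        assert est2.get_params() == params
        est2.set_params(method="st")
        assert est2.method == "st"

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = clone(PLAMRegressor(n_parametric=1, grid_len=10))
        assert est.grid_len == 10
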