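import numpy as np
import pandas as pd
import pytest

from phylodisp import pglmm
from phylodisp import trees as ph
from phylodisp.simulate import SimulationConfig, simulate_dataset, simulate_tree


def _random_instance(seed, n=15, p=3):
    """Small random dataset on a simulated tree."""
    rng = np.random.default_rng(seed)
    tree, _ = simulate_tree(n, 1, 1.0, seed=seed)
    C = ph.phylo_vcv(tree, correlation=True).values()
    X = rng.standard_normal((n, p))
    beta = rng.normal(0, 1, p + 1)
    L = np.linalg.cholesky(0.5 * C + 0.5 * np.eye(n) + 1e-10 * np.eye(n))
    y = beta[0] + X @ beta[1:] + L @ rng.standard_normal(n)
    return y, X, C


def naive_loglik(beta, s2p, s2e, y, X, C):
    """Dense-inverse oracle for the multivariate normal log density."""
    V = s2p * C + s2e * np.eye(len(y))
    r = y - X @ beta
    return float(
        -0.5 * (len(y) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                + r @ np.linalg.inv(V) @ r)
    )


class TestLoglik:
    def test_standard_normal_at_mean(self):
        ll = pglmm.loglik([0.0], 0.0, 1.0, np.array([0.0]), np.array([[1.0]]),
                          np.array([[1.0]]))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_inverse_oracle(self, seed):
        y, X, C = _random_instance(seed)
        Xi = np.column_stack([np.ones(len(y)), X])
        rng = np.random.default_rng(seed + 100)
        beta = rng.normal(0, 1, Xi.shape[1])
        ll = pglmm.loglik(beta, 0.7, 0.6, y, Xi, C)
        assert ll == pytest.approx(naive_loglik(beta, 0.7, 0.6, y, Xi, C), abs=1e-8)

    def test_scale_invariant_quadratic_form(self):
        y, X, C = _random_instance(3)
        Xi = np.column_stack([np.ones(len(y)), X])
        beta = np.zeros(Xi.shape[1])
        for c in [1.0, 10.0]:
            n = len(y)
            ll = pglmm.loglik(beta, 0.5 * c ** 2, 0.5 * c ** 2, c * y, Xi, C)
            base = pglmm.loglik(beta, 0.5, 0.5, y, Xi, C)
            # scaling y and variances together shifts ll only by the Jacobian
            assert ll == pytest.approx(base - n * np.log(c), abs=1e-8)

    def test_invalid_variances(self):
        y, X, C = _random_instance(1)
        with pytest.raises(ValueError):
            pglmm.loglik(np.zeros(4), -0.1, 1.0, y,
                         np.column_stack([np.ones(len(y)), X]), C)


class TestFit:
    def test_identity_C_collapses_to_ols(self, rng):
        n, p = 40, 3
        X = rng.standard_normal((n, p))
        y = 1.0 + X @ np.array([0.5, -0.3, 0.0]) + rng.standard_normal(n)
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = pglmm.fit_pglmm(y, X, np.eye(n))
        Xi = np.column_stack([np.ones(n), X])
        beta_ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, atol=1e-8)
        assert fit.degenerate
        assert fit.lam == 0.0

    def test_profile_optimum_beats_grid(self):
        data = simulate_dataset(SimulationConfig(n=60, seed=21))
        fit = pglmm.fit_pglmm(data["response"], data["traits"], data["cov"])
        yv = data["response"].to_numpy()
        Xv = fit.X_.to_numpy()
        grid = np.linspace(0, 1 - 1e-9, 101)
        lls = [pglmm._profile(r, yv, Xv, fit.C_)[0] for r in grid]
        assert fit.loglik >= max(lls) - 1e-6

    def test_loglik_at_zero_rho_equals_linear_model(self):
        y, X, C = _random_instance(7)
        Xi = np.column_stack([np.ones(len(y)), X])
        ll0 = pglmm._profile(0.0, y, Xi, C)[0]
        beta = np.linalg.lstsq(Xi, y, rcond=None)[0]
        s2 = np.mean((y - Xi @ beta) ** 2)
        n = len(y)
        ols_ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
        assert ll0 == pytest.approx(ols_ll, abs=1e-10)

    def test_lambda_invariant_to_response_scale_and_C_scaling(self):
        data = simulate_dataset(SimulationConfig(n=80, seed=5))
        y = data["response"]
        X = data["traits"]
        C = data["cov"].values()
        f1 = pglmm.fit_pglmm(y, X, C)
        f2 = pglmm.fit_pglmm(3.7 * y, X, C)
        assert f1.lam == pytest.approx(f2.lam, abs=1e-6)
        f3 = pglmm.fit_pglmm(y, X, 4.0 * C)  # rescaled internally
        assert f1.lam == pytest.approx(f3.lam, abs=1e-6)

    def test_gls_oracle_equivalence_small_n(self):
        for seed in range(5):
            y, X, C = _random_instance(seed, n=18)
            Xi = np.column_stack([np.ones(len(y)), X])
            rho = 0.4
            W = rho * C + (1 - rho) * np.eye(len(y))
            beta_prof = pglmm._profile(rho, y, Xi, C)[1]
            Winv = np.linalg.inv(W)
            beta_dense = np.linalg.solve(Xi.T @ Winv @ Xi, Xi.T @ Winv @ y)
            np.testing.assert_allclose(beta_prof, beta_dense, atol=1e-8)

    def test_rejects_misaligned_inputs(self):
        y, X, C = _random_instance(2)
        with pytest.raises(ValueError):
            pglmm.fit_pglmm(y[:-1], X, C)

    def test_rejects_non_psd(self):
        y, X, _ = _random_instance(2)
        n = len(y)
        bad = -np.eye(n)
        with pytest.raises(ValueError):
            pglmm.fit_pglmm(y, X, bad)


class TestR2:
    def test_intercept_only_zero_marginal(self):
        data = simulate_dataset(SimulationConfig(n=50, seed=2))
        fit = pglmm.fit_pglmm(data["response"], pd.DataFrame(index=data["response"].index),
                              data["cov"])
        assert fit.r2_marginal == pytest.approx(0.0, abs=1e-12)
        assert fit.r2_conditional >= fit.r2_marginal

    def test_zero_phylo_variance_equalizes(self, rng):
        n = 60
        X = rng.standard_normal((n, 2))
        y = X @ np.array([1.0, -0.5]) + rng.standard_normal(n)
        with pytest.warns(UserWarning):
            fit = pglmm.fit_pglmm(y, X, np.eye(n))
        assert fit.sigma2_phylo == pytest.approx(0.0, abs=1e-12)
        assert fit.r2_marginal == pytest.approx(fit.r2_conditional, abs=1e-12)

    def test_recovers_generative_variance_ratio(self):
        # large-n plug-in check: R2m ~ var(Xb) / (var(Xb) + sigma2)
        data = simulate_dataset(SimulationConfig(n=1200, seed=42))
        fit = pglmm.fit_pglmm(data["response"], data["traits"], data["cov"])
        beta = np.array([0.5, -0.4, -0.2])
        Xsub = data["traits"][["body_mass", "life_history", "breeding_latitude"]]
        var_fix = np.var(Xsub.to_numpy() @ beta, ddof=1)
        truth = var_fix / (var_fix + 1.0)
        assert fit.r2_marginal == pytest.approx(truth, abs=0.05)


class TestPredict:
    @pytest.fixture(scope="class")
    def fit(self):
        data = simulate_dataset(SimulationConfig(n=60, seed=13))
        return pglmm.fit_pglmm(data["response"], data["traits"], data["cov"]), data

    def test_training_rows_reproduce_fitted(self, fit):
        f, data = fit
        pred = pglmm.predict_marginal(f, data["traits"].iloc[:5])
        np.testing.assert_allclose(pred, f.fitted.iloc[:5], atol=1e-12)

    def test_zero_row_gives_intercept(self, fit):
        f, data = fit
        zero = pd.DataFrame(0.0, index=["new"], columns=data["traits"].columns)
        assert pglmm.predict_marginal(f, zero)[0] == pytest.approx(f.beta["(Intercept)"])

    def test_linearity_superposition(self, fit):
        f, data = fit
        a = data["traits"].iloc[[0]].to_numpy()
        b = data["traits"].iloc[[1]].to_numpy()
        pa = pglmm.predict_marginal(f, a)[0] - f.beta["(Intercept)"]
        pb = pglmm.predict_marginal(f, b)[0] - f.beta["(Intercept)"]
        pab = pglmm.predict_marginal(f, a + b)[0] - f.beta["(Intercept)"]
        assert pab == pytest.approx(pa + pb, abs=1e-10)

    def test_zero_cross_covariance_equals_marginal(self, fit):
        f, data = fit
        Xn = data["traits"].iloc[:4]
        cc = np.zeros((4, f.n))
        np.testing.assert_allclose(
            pglmm.predict_conditional(f, Xn, cc), pglmm.predict_marginal(f, Xn), atol=1e-12
        )

    def test_interpolation_limit_for_phylogenetic_twin(self):
        # nearly noise-free response: conditional prediction at a training
        # species' own phylogenetic position returns its observed value
        data = simulate_dataset(SimulationConfig(n=40, seed=3, lam=0.98))
        f = pglmm.fit_pglmm(data["response"], data["traits"], data["cov"])
        i = 7
        cc = f.C_[[i], :]
        pred = pglmm.predict_conditional(f, data["traits"].iloc[[i]], cc)[0]
        obs = data["response"].iloc[i]
        resid_scale = np.sqrt(f.sigma2_resid) + 1e-3
        assert abs(pred - obs) < 5 * resid_scale

    def test_conditional_beats_marginal_at_high_lambda(self):
        wins = 0
        for seed in range(8):
            data = simulate_dataset(SimulationConfig(n=80, seed=100 + seed, lam=0.9))
            y = data["response"].to_numpy()
            # interleaved split: held-out species keep close relatives in training
            te = np.arange(0, 80, 4)
            tr = np.setdiff1d(np.arange(80), te)
            f = pglmm.fit_pglmm(y[tr], data["traits"].iloc[tr],
                                data["cov"].values()[np.ix_(tr, tr)])
            Xte = data["traits"].iloc[te]
            cc = data["cov"].values()[np.ix_(te, tr)]
            mse_m = np.mean((pglmm.predict_marginal(f, Xte) - y[te]) ** 2)
            mse_c = np.mean((pglmm.predict_conditional(f, Xte, cc) - y[te]) ** 2)
            wins += mse_c < mse_m
        assert wins >= 6


class TestSampler:
    def test_posterior_agrees_with_profile_ml(self):
        data = simulate_dataset(SimulationConfig(n=50, seed=8))
        fit = pglmm.fit_pglmm(data["response"], data["traits"], data["cov"])
        draws, diag = pglmm.sample_posterior(
            data["response"], data["traits"], data["cov"],
            chains=2, iterations=400, warmup=200, seed=1,
        )
        assert 0 < diag["acceptance_rate"] < 1
        post_mean = draws["body_mass"].mean()
        assert post_mean == pytest.approx(fit.beta["body_mass"], abs=3 * fit.se["body_mass"])


def test_parametric_bootstrap_brackets_truth():
    data = simulate_dataset(SimulationConfig(n=60, seed=4))
    fit = pglmm.fit_pglmm(data["response"], data["traits"], data["cov"])
    ci = pglmm.parametric_bootstrap_ci(fit, replicates=60, seed=0)
    assert (ci["ci_low"] <= ci["estimate"]).all()
    assert (ci["estimate"] <= ci["ci_high"]).all()


def test_lambda_pi2_compat_smaller_than_variance_ratio():
    data = simulate_dataset(SimulationConfig(n=60, seed=9))
    fit = pglmm.fit_pglmm(data["response"], data["traits"], data["cov"])
    # with pi^2/3 ~ 3.29 replacing a sub-unit residual variance the statistic shrinks
    assert pglmm.lambda_pi2_compat(fit) < fit.lam
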