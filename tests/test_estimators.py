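import numpy as np
import pytest
from scipy import integrate, stats

from effectome import (
    ConfounderSpec,
    ConnectomePrior,
    ConvergenceConfig,
    convergence_experiment,
    iv_2sls,
    iv_bayes_map,
    log_evidence,
    make_confounded_pair,
    ols_weights,
    recovery_metrics,
    select_hyperparams,
    simulate_var1,
)
from effectome.exceptions import ConfigError, RankError


class TestOLS:
    def test_exact_noise_free_regression(self):
        x = np.linspace(-1, 1, 50)
        res = ols_weights(x, 2 * x)
        assert res.W_hat[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert res.metrics["rss"] == pytest.approx(0.0, abs=1e-12)

    def test_attenuation_under_shared_latent(self):
        """X = Z + e, Y = Z with unit variances: slope converges to 1/2."""
        rng = np.random.default_rng(0)
        z = rng.standard_normal(200_000)
        x = z + rng.standard_normal(200_000)
        res = ols_weights(x, z)
        assert res.W_hat[0, 0] == pytest.approx(0.5, abs=0.01)

    def test_confounded_bias_does_not_vanish(self):
        """With a slow shared input and true weight 0, the OLS estimate is
        bounded away from zero at every sample size."""
        for n in (1_000, 10_000, 100_000):
            rec = make_confounded_pair(
                ConfounderSpec(amplitude=0.2, persistence=0.995),
                beta=0.0, n_samples=n, seed=n,
            )
            L, X, Y = rec.iv_arrays()
            slope = ols_weights(X, Y[:, 1]).W_hat[0, 0]
            assert abs(slope) > 0.2

    def test_rank_deficiency_suggests_pinv(self):
        x = np.ones((30, 2))  # two identical columns
        y = np.arange(30.0)
        with pytest.raises(RankError, match="pinv"):
            ols_weights(x, y)
        res = ols_weights(x, y, use_pinv=True)
        assert res.W_hat.shape == (1, 2)


class TestIV2SLS:
    def test_perfect_first_stage_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        L = rng.standard_normal(500)
        Y = 1.5 * L + 0.1 * rng.standard_normal(500)
        iv = iv_2sls(L, L, Y, mode="two-stage")
        ols = ols_weights(L, Y)
        np.testing.assert_allclose(iv.W_hat, ols.W_hat, atol=1e-10)

    def test_confounded_pair_converges_to_zero(self):
        """IV removes the confounding bias that OLS keeps (true weight 0)."""
        rec = make_confounded_pair(
            ConfounderSpec(amplitude=0.2, persistence=0.995),
            beta=0.0, n_samples=100_000, seed=7,
        )
        L, X, Y = rec.iv_arrays()
        iv = iv_2sls(L, X, Y[:, 1]).W_hat[0, 0]
        ols = ols_weights(X, Y[:, 1]).W_hat[0, 0]
        assert abs(iv) < 0.02
        assert abs(ols) > 10 * abs(iv)

    def test_recovers_downstream_column_of_small_circuit(self):
        """Stimulating neuron 1 of a 3-neuron circuit recovers its outgoing
        weights within 3 standard errors at n = 1e5."""
        W = np.array([[0.0, 0.1, 0.0], [0.5, 0.0, 0.0], [0.2, 0.1, 0.1]])
        rec = simulate_var1(
            W, n_steps=100_001, source_ids=[0], noise_scale=1.0,
            laser_variance=10.0, seed=11,
        )
        L, X, Y = rec.iv_arrays()
        est = iv_2sls(L, X, Y).W_hat[:, 0]
        n, l = 100_000, 10.0
        for i, (got, want) in enumerate(zip(est, W[:, 0])):
            se = np.sqrt(rec.R[:, i].var() / (n * l))
            assert abs(got - want) < 3 * se, f"target {i}"

    def test_covariance_identity_for_first_stage(self):
        """Sample Cov(X_t, L_t) approaches W_lx (here the identity map on
        two lasers) within 3 standard errors on a 5-neuron system."""
        W = np.triu(np.full((5, 5), 0.1), 1)
        rec = simulate_var1(
            W, n_steps=100_001, source_ids=[0, 3], noise_scale=1.0,
            laser_variance=1.0, seed=13,
        )
        L, X, Y = rec.iv_arrays()
        cxl = (X - X.mean(0)).T @ (L - L.mean(0)) / len(L)
        se = np.sqrt(2.0 / len(L))  # Var(x l) ~ Var(x)Var(l) ~ 2
        np.testing.assert_allclose(cxl, np.eye(2), atol=3 * se)

    def test_modes_agree_square_full_rank(self):
        rng = np.random.default_rng(3)
        L = rng.standard_normal((4000, 2))
        X = L @ np.array([[1.0, 0.3], [0.2, 0.8]]) + 0.1 * rng.standard_normal((4000, 2))
        Y = X @ np.array([[0.5], [-0.7]]).T[0] + 0.1 * rng.standard_normal(4000)
        a = iv_2sls(L, X, Y, mode="covariance")
        b = iv_2sls(L, X, Y, mode="two-stage")
        np.testing.assert_allclose(a.W_hat, b.W_hat, atol=1e-8)

    def test_unidentified_source_raises_rank_error(self):
        """Two lasers whose effects on the two sources are collinear leave
        the first stage rank deficient."""
        rng = np.random.default_rng(4)
        L = rng.standard_normal((300, 2))
        X = np.column_stack([L[:, 0], 2.0 * L[:, 0]])
        Y = rng.standard_normal(300)
        with pytest.raises(RankError, match="rank"):
            iv_2sls(L, X, Y)


class TestIVBayes:
    def _toy_problem(self, seed=0, n=600, n_s=3, n_y=4):
        rng = np.random.default_rng(seed)
        L = rng.standard_normal((n, n_s))
        B = rng.standard_normal((n_s, n_s)) * 0.3 + np.eye(n_s)
        X = L @ B + 0.2 * rng.standard_normal((n, n_s))
        W = rng.standard_normal((n_y, n_s)) * 0.5
        Y = X @ W.T + 0.3 * rng.standard_normal((n, n_y))
        return L, X, Y, W

    def test_vague_prior_limit_matches_2sls(self):
        L, X, Y, _ = self._toy_problem()
        prior = ConnectomePrior.isotropic(np.zeros((4, 3)), gamma2=1e12, sigma2=1.0)
        bayes = iv_bayes_map(L, X, Y, prior)
        iv = iv_2sls(L, X, Y, mode="two-stage")
        np.testing.assert_allclose(bayes.W_hat, iv.W_hat, atol=1e-8)

    def test_zero_samples_returns_prior_mean(self):
        mu = np.array([[1.0, -2.0]])
        prior = ConnectomePrior.isotropic(mu, gamma2=0.5)
        res = iv_bayes_map(
            np.empty((0, 2)), np.empty((0, 2)), np.empty((0, 1)), prior
        )
        np.testing.assert_array_equal(res.W_hat, mu)

    def test_single_predictor_closed_form(self):
        """x=(1,2), y=(2,4), mu=0, sigma^2=gamma^2=1: the ridge solution
        (X'X + I)^{-1} X'Y = 10/6."""
        x = np.array([1.0, 2.0])
        y = np.array([2.0, 4.0])
        prior = ConnectomePrior.isotropic(np.zeros((1, 1)), gamma2=1.0, sigma2=1.0)
        res = iv_bayes_map(x, x, y, prior, demean=False)
        assert res.W_hat[0, 0] == pytest.approx(10 / 6, abs=1e-12)

    def test_map_equals_dense_normal_equations_oracle(self):
        """The per-target solver matches a brute-force regularized solve."""
        for seed in range(5):
            L, X, Y, _ = self._toy_problem(seed=seed)
            rng = np.random.default_rng(100 + seed)
            mu = rng.standard_normal((4, 3))
            var = rng.uniform(0.1, 2.0, size=(4, 3))
            prior = ConnectomePrior(mean=mu, variance=var, sigma2=0.7)
            res = iv_bayes_map(L, X, Y, prior)
            # oracle: explicit dense solve per target on the fitted X-hat
            Lc = L - L.mean(0)
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            B1 = np.linalg.lstsq(Lc, Xc, rcond=None)[0]
            Xh = Lc @ B1
            for j in range(4):
                A = Xh.T @ Xh / 0.7 + np.diag(1.0 / var[j])
                b = Xh.T @ Yc[:, j] / 0.7 + mu[j] / var[j]
                np.testing.assert_allclose(
                    res.W_hat[j], np.linalg.solve(A, b), atol=1e-8
                )

    def test_nonpositive_prior_variance_rejected(self):
        with pytest.raises(ConfigError, match="positive"):
            ConnectomePrior(mean=np.zeros((1, 1)), variance=np.zeros((1, 1)))

    def test_wrong_prior_mean_still_consistent(self):
        """With a deliberately wrong prior mean and fixed positive variance,
        the estimate still converges to the truth as n grows."""
        rng = np.random.default_rng(21)
        w_true = 0.8
        errs = []
        for n in (200, 2_000, 20_000):
            L = rng.standard_normal(n)
            X = L + 0.2 * rng.standard_normal(n)
            Y = w_true * X + 0.3 * rng.standard_normal(n)
            prior = ConnectomePrior.isotropic([[-5.0]], gamma2=0.05, sigma2=1.0)
            res = iv_bayes_map(L, X, Y, prior)
            errs.append(abs(res.W_hat[0, 0] - w_true))
        assert errs[2] < errs[0]
        assert errs[2] < 0.05


class TestHyperparamSelection:
    def test_evidence_matches_quadrature_1d(self):
        """Closed-form log evidence equals numerical integration over w."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(12)
        y = 0.5 * x + 0.3 * rng.standard_normal(12)
        mu, v, s2 = 0.2, 0.8, 0.3

        def integrand(w):
            lik = np.prod(stats.norm.pdf(y, loc=w * x, scale=np.sqrt(s2)))
            return lik * stats.norm.pdf(w, loc=mu, scale=np.sqrt(v))

        quad, _ = integrate.quad(integrand, -20, 20, limit=200)
        closed = log_evidence(x[:, None], y, [mu], [v], s2)
        assert closed == pytest.approx(np.log(quad), abs=1e-6)

    def test_point_prior_limit_is_likelihood_at_mu(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20)
        y = 0.4 * x + 0.1 * rng.standard_normal(20)
        mu, s2 = 0.4, 0.5
        ev = log_evidence(x[:, None], y, [mu], [1e-14], s2)
        loglik = stats.norm.logpdf(y, loc=mu * x, scale=np.sqrt(s2)).sum()
        assert ev == pytest.approx(loglik, abs=1e-4)

    def test_evidence_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(7)
        L = rng.standard_normal(100)
        X = L + 0.1 * rng.standard_normal(100)
        Y = 0.3 * X + 0.2 * rng.standard_normal(100)

        def family(gamma2, sigma2):
            return ConnectomePrior.isotropic([[0.0]], gamma2=gamma2, sigma2=sigma2)

        grid = [{"gamma2": g, "sigma2": 0.2} for g in (0.01, 0.1, 1.0)]
        _, surf1 = select_hyperparams(L, X, Y, family, grid)
        perm = np.random.default_rng(0).permutation(100)
        _, surf2 = select_hyperparams(L[perm], X[perm], Y[perm], family, grid)
        np.testing.assert_allclose(
            surf1["score"].to_numpy(), surf2["score"].to_numpy(), atol=1e-8
        )

    def test_grid_cv_picks_reasonable_scale(self):
        rng = np.random.default_rng(8)
        L = rng.standard_normal(400)
        X = L + 0.1 * rng.standard_normal(400)
        Y = 0.5 * X + 0.2 * rng.standard_normal(400)

        def family(gamma2, sigma2):
            return ConnectomePrior.isotropic([[0.0]], gamma2=gamma2, sigma2=sigma2)

        grid = [{"gamma2": g, "sigma2": 0.04} for g in (1e-6, 1.0)]
        theta, _ = select_hyperparams(L, X, Y, family, grid, method="grid-cv")
        assert theta["gamma2"] == 1.0  # the point prior at 0 predicts badly

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            select_hyperparams(
                np.ones(3), np.ones(3), np.ones(3), lambda **k: None, []
            )


class TestRecoveryMetrics:
    def test_perfect_recovery(self):
        w = np.array([[1.0, -2.0], [0.5, 0.0]])
        m = recovery_metrics(w, w)
        assert m["rss"] == 0.0 and m["r2"] == 1.0

    def test_null_predictor_zero_mean_truth(self):
        w = np.array([1.0, -1.0])
        m = recovery_metrics(np.zeros(2), w)
        assert m["r2"] == pytest.approx(0.0)

    def test_hand_rss(self):
        m = recovery_metrics(np.array([1.0, 0.0]), np.array([1.0, 2.0]))
        assert m["rss"] == pytest.approx(4.0)

    def test_constant_truth_r2_missing(self):
        m = recovery_metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
        assert m["r2"] is None and m["rss"] == pytest.approx(5.0)


@pytest.fixture(scope="module")
def tiny_result():
    cfg = ConvergenceConfig(
        d=150, sparsity=0.05, scale_s=1e-3,
        sample_sizes=(500, 5_000), n_replicates=3, seed=5,
    )
    return convergence_experiment(cfg), cfg


class TestConvergenceExperiment:
    def test_records_complete_and_seeded(self, tiny_result):
        res, cfg = tiny_result
        assert len(res.records) == 2 * 2 * 3  # estimators x sizes x replicates
        rerun = convergence_experiment(cfg)
        np.testing.assert_array_equal(
            res.records["rss"].to_numpy(), rerun.records["rss"].to_numpy()
        )

    def test_mean_rss_nonincreasing_in_samples(self, tiny_result):
        res, _ = tiny_result
        for est, grp in res.records.groupby("estimator"):
            means = grp.groupby("n_samples")["rss"].mean().sort_index()
            assert means.iloc[-1] <= means.iloc[0]

    def test_bayes_beats_raw_iv_everywhere(self, tiny_result):
        res, _ = tiny_result
        piv = res.records.pivot_table(
            index="n_samples", columns="estimator", values="rss", aggfunc="mean"
        )
        assert (piv["iv-bayes"] < piv["iv"]).all()
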