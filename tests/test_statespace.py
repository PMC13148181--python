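import numpy as np
import pytest
from scipy import stats

from svtvpfavar.statespace import (
    KSC_MEANS,
    KSC_OFFSET,
    KSC_PROBS,
    KSC_VARS,
    LinearGaussianSS,
    RandomWalkBlockLaw,
    carter_kohn_sample,
    draw_inverse_wishart,
    kalman_filter,
    kalman_smoother,
    sample_q_blocks,
    sample_sv_ksc,
)


def random_instance(rng, T=None, ny=None, ns=None):
    """A random small identity-transition state-space model with data."""
    T = T or rng.integers(3, 9)
    ny = ny or rng.integers(1, 3)
    ns = ns or rng.integers(1, 4)
    Z = rng.normal(size=(T, ny, ns))
    H = np.empty((T, ny, ny))
    for t in range(T):
        A = rng.normal(size=(ny, ny + 1))
        H[t] = A @ A.T + 0.3 * np.eye(ny)
    Aq = rng.normal(size=(ns, ns + 1))
    Q = 0.3 * (Aq @ Aq.T / (ns + 1))
    a0 = rng.normal(size=ns)
    P0 = np.eye(ns) * rng.uniform(0.5, 2.0)
    model = LinearGaussianSS(Z, H, Q, a0, P0)
    y = rng.normal(size=(T, ny))
    return model, y


def joint_gaussian_loglik(model, y):
    """Oracle: the log density of y under the stacked T*ny-dimensional
    Gaussian implied by the random-walk state-space model."""
    T, ny, ns = model.obs_matrices.shape
    mean = np.concatenate([model.obs_matrices[t] @ model.init_mean for t in range(T)])
    cov = np.zeros((T * ny, T * ny))
    for t in range(T):
        for u in range(T):
            # states s_t = s_0 + w_1 + ... + w_t, s_0 ~ N(a0, P0)
            state_cov = model.init_cov + (1 + min(t, u)) * model.state_cov
            block = model.obs_matrices[t] @ state_cov @ model.obs_matrices[u].T
            if t == u:
                block = block + model.obs_cov[t]
            cov[t * ny : (t + 1) * ny, u * ny : (u + 1) * ny] = block
    return stats.multivariate_normal.logpdf(y.ravel(), mean=mean, cov=cov)


class TestKalmanFilter:
    def test_loglik_matches_joint_gaussian_oracle(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(50):
            model, y = random_instance(rng)
            _, _, ll = kalman_filter(model, y)
            worst = max(worst, abs(ll - joint_gaussian_loglik(model, y)))
        assert worst < 1e-8

    def test_static_state_filtered_mean_is_running_average(self):
        rng = np.random.default_rng(1)
        T = 40
        y = rng.normal(size=(T, 1))
        model = LinearGaussianSS(
            np.ones((T, 1, 1)),
            np.ones((T, 1, 1)),
            np.zeros((1, 1)),
            np.zeros(1),
            1e8 * np.eye(1),
        )
        att, _, _ = kalman_filter(model, y)
        running = np.cumsum(y[:, 0]) / np.arange(1, T + 1)
        np.testing.assert_allclose(att[:, 0], running, atol=1e-4)

    def test_perfect_observation_pins_state_to_data(self):
        rng = np.random.default_rng(2)
        T = 20
        y = rng.normal(size=(T, 2))
        model = LinearGaussianSS(
            np.broadcast_to(np.eye(2), (T, 2, 2)).copy(),
            np.broadcast_to(1e-12 * np.eye(2), (T, 2, 2)).copy(),
            0.5 * np.eye(2),
            np.zeros(2),
            np.eye(2),
        )
        att, _, _ = kalman_filter(model, y)
        np.testing.assert_allclose(att, y, atol=1e-4)

    def test_filtered_covariances_symmetric_pd(self):
        rng = np.random.default_rng(3)
        model, y = random_instance(rng, T=8, ny=2, ns=3)
        _, Ptt, _ = kalman_filter(model, y)
        for P in Ptt:
            assert np.max(np.abs(P - P.T)) < 1e-10
            np.linalg.cholesky(P + 1e-12 * np.eye(3))


class TestCarterKohn:
    def test_zero_state_cov_gives_exactly_constant_path(self):
        rng = np.random.default_rng(4)
        model, y = random_instance(rng, T=15, ny=1, ns=2)
        model = LinearGaussianSS(
            model.obs_matrices,
            model.obs_cov,
            np.zeros((2, 2)),
            model.init_mean,
            model.init_cov,
        )
        path = carter_kohn_sample(model, y, np.random.default_rng(5))
        assert (path == path[0]).all()

    def test_draw_mean_matches_smoother_mean(self):
        rng = np.random.default_rng(6)
        T = 30
        truth = np.cumsum(rng.normal(0, 0.3, T))
        y = (truth + rng.normal(0, 0.5, T))[:, None]
        model = LinearGaussianSS(
            np.ones((T, 1, 1)),
            np.full((T, 1, 1), 0.25),
            np.array([[0.09]]),
            np.zeros(1),
            np.eye(1) * 4.0,
        )
        draws = np.array(
            [carter_kohn_sample(model, y, rng)[:, 0] for _ in range(3000)]
        )
        smoothed, _ = kalman_smoother(model, y)
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - smoothed[:, 0]) < 3 * mc_se + 1e-6)

    def test_uninformative_data_reproduces_prior_random_walk(self):
        rng = np.random.default_rng(7)
        T, q = 25, 0.04
        y = rng.normal(size=(T, 1))
        model = LinearGaussianSS(
            np.ones((T, 1, 1)),
            np.full((T, 1, 1), 1e8),
            np.array([[q]]),
            np.zeros(1),
            np.array([[1e-12]]),
        )
        draws = np.array(
            [carter_kohn_sample(model, y, rng)[:, 0] for _ in range(3000)]
        )
        var = draws.var(axis=0, ddof=1)
        t_idx = np.arange(1, T + 1)
        expected = q * t_idx
        # chi-square MC error on the variance estimate
        se = expected * np.sqrt(2.0 / len(draws))
        assert np.all(np.abs(var - expected) < 4 * se + 1e-4)


class TestKSCMixture:
    def test_table_is_a_probability_mixture(self):
        assert abs(KSC_PROBS.sum() - 1.0) < 1e-12
        assert (KSC_VARS > 0).all()

    def test_mixture_mean_matches_log_chi_square(self):
        # E[log chi2_1] = psi(1/2) + log 2
        from scipy.special import digamma

        target = digamma(0.5) + np.log(2.0)
        mix_mean = (KSC_PROBS * (KSC_MEANS - KSC_OFFSET)).sum()
        assert abs(mix_mean - target) < 1e-3

    def test_constant_volatility_level_recovered(self):
        law = RandomWalkBlockLaw(time_varying=True, q=0.01, init_mean=0.0, init_cov=4.0)
        levels = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            e = rng.standard_normal(500)  # true sigma^2 = 1
            h = None
            keep = []
            for it in range(200):
                h = sample_sv_ksc(e, law, rng, h_current=h)
                if it >= 100:
                    keep.append(np.exp(2 * h).mean())
            levels.append(np.mean(keep))
        assert 0.8 < np.mean(levels) < 1.25

    def test_step_change_in_volatility_is_tracked(self):
        rng = np.random.default_rng(11)
        T = 300
        sig = np.where(np.arange(T) < T // 2, 1.0, 3.0)
        e = sig * rng.standard_normal(T)
        law = RandomWalkBlockLaw(time_varying=True, q=0.02, init_mean=0.0, init_cov=4.0)
        h = None
        keep = []
        for it in range(400):
            h = sample_sv_ksc(e, law, rng, h_current=h)
            if it >= 150:
                keep.append(h)
        h_mean = np.mean(keep, axis=0)
        assert np.corrcoef(h_mean, np.log(sig))[0, 1] > 0.7

    def test_zero_residuals_rejected(self):
        law = RandomWalkBlockLaw()
        with pytest.raises(ValueError):
            sample_sv_ksc(np.zeros(50), law, np.random.default_rng(0))


class TestInverseWishart:
    def test_every_draw_symmetric_pd(self):
        rng = np.random.default_rng(12)
        scale = np.array([[2.0, 0.4], [0.4, 1.0]])
        for _ in range(200):
            d = draw_inverse_wishart(scale, 6, rng)
            assert np.max(np.abs(d - d.T)) < 1e-10
            np.linalg.cholesky(d)

    def test_mean_matches_closed_form(self):
        rng = np.random.default_rng(13)
        scale = np.array([[2.0, 0.5], [0.5, 1.5]])
        dof = 10
        draws = stats.invwishart.rvs(df=dof, scale=scale, size=20000, random_state=rng)
        expected = scale / (dof - 2 - 1)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)

    def test_scalar_reduces_to_inverse_gamma(self):
        rng = np.random.default_rng(14)
        dof, scale = 7, 2.5
        draws = np.array(
            [draw_inverse_wishart(np.array([[scale]]), dof, rng)[0, 0] for _ in range(2000)]
        )
        _, p = stats.kstest(draws, stats.invgamma(a=dof / 2, scale=scale / 2).cdf)
        assert p > 0.01

    def test_invalid_dof_rejected(self):
        with pytest.raises(ValueError):
            draw_inverse_wishart(np.eye(3), 1.5, np.random.default_rng(0))


class TestQBlocks:
    def test_no_data_reproduces_the_prior(self):
        rng = np.random.default_rng(15)
        prior_scale = np.array([[1.2, 0.2], [0.2, 0.8]])
        dof = 10
        post = np.array(
            [
                sample_q_blocks(np.empty((0, 2)), prior_scale, dof, rng)
                for _ in range(10000)
            ]
        )
        prior = stats.invwishart.rvs(
            df=dof, scale=prior_scale, size=10000, random_state=rng
        )
        se = prior.std(axis=0, ddof=1) / np.sqrt(len(prior)) * np.sqrt(2)
        assert np.all(np.abs(post.mean(axis=0) - prior.mean(axis=0)) < 4 * se)

    def test_long_sample_recovers_known_q(self):
        rng = np.random.default_rng(16)
        Q = np.array([[0.04, 0.01], [0.01, 0.09]])
        inc = rng.multivariate_normal(np.zeros(2), Q, size=2000)
        draws = np.array(
            [sample_q_blocks(inc, 0.01 * np.eye(2), 3, rng) for _ in range(500)]
        )
        rel = np.abs(draws.mean(axis=0) - Q) / np.abs(Q)
        assert np.all(rel < 0.10)
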