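import numpy as np
import pytest

from svtvpfavar.diagnostics import (
    _parzen_weights,
    geweke_z,
    inefficiency_factor,
    posterior_summary,
)
from svtvpfavar.factors import IdiosyncraticModel, extract_factors_pca
from svtvpfavar.gibbs import (
    ModelDims,
    PriorConfig,
    SamplerConfig,
    _identify_factors,
    run_gibbs,
)
from svtvpfavar.preprocess import standardize
from svtvpfavar.simulate import (
    ScenarioConfig,
    sign_switch_preset,
    simulate_tvp_favar,
    small_tvp_var_preset,
)


class TestPriors:
    def test_q_prior_scale_constants(self):
        """The Q priors follow the stated inverse-Wishart configuration:
        scale 0.005 (dim+1) Vhat for Q_B, 0.01 (dim+1) I per alpha block,
        0.0001 (dim+1) I for Q_sigma, each with dof = dim + 1."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=(60, 3))
        dims = ModelDims(k=1, l=1, p=2, T=60)
        pri = PriorConfig.minnesota(y, dims)
        mb = dims.mb
        scale, dof = pri.q_b_prior()
        np.testing.assert_allclose(scale, 0.005 * (mb + 1) * pri.b0_cov)
        assert dof == mb + 1
        scale_a, dof_a = pri.q_a_prior(2)
        np.testing.assert_allclose(scale_a, 0.01 * 3 * np.eye(2))
        assert dof_a == 3
        scale_s, dof_s = pri.q_s_prior(3)
        np.testing.assert_allclose(scale_s, 0.0001 * 4 * np.eye(3))
        assert dof_s == 4

    def test_minnesota_structure(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(80, 2))
        dims = ModelDims(k=1, l=0, p=2, T=80)
        pri = PriorConfig.minnesota(y, dims)
        m = 2
        mean = pri.b0_mean
        # own first lags at 0.9, everything else 0
        own_first = [j * m + j for j in range(m)]
        for pos in range(dims.mb):
            assert mean[pos] == (0.9 if pos in own_first else 0.0)
        var = np.diag(pri.b0_cov)
        # second-lag variances shrink by the lag-decay factor
        assert var[m * m + 0] == pytest.approx(var[0] / 4)


class TestSampler:
    def test_same_seed_same_draws(self, small_dataset):
        dims = ModelDims(k=1, l=1, p=1, q=0, T=80)
        cfg = SamplerConfig(n_draws=80, n_burn=40, thin=2, seed=3)
        a = run_gibbs(small_dataset.y, dims, sampler=cfg)
        b = run_gibbs(small_dataset.y, dims, sampler=cfg)
        np.testing.assert_array_equal(a.b_path, b.b_path)
        np.testing.assert_array_equal(a.sigma_path, b.sigma_path)
        assert a.n_retained == (80 - 40) // 2

    def test_fixed_coefficient_reduction_matches_ols(self):
        """With all time-variation indicators off and homoskedastic errors,
        the sampler is a constant-parameter Bayesian VAR whose posterior
        sits on the least-squares estimate."""
        rng = np.random.default_rng(11)
        T0, m = 300, 2
        B = np.array([[0.5, 0.1], [-0.2, 0.7]])
        y = np.zeros((T0, m))
        for t in range(1, T0):
            y[t] = B @ y[t - 1] + rng.standard_normal(m)
        dims = ModelDims(k=1, l=0, p=1, q=0, T=T0)
        draws = run_gibbs(
            y,
            dims,
            priors=PriorConfig.diffuse(dims),
            sampler=SamplerConfig(
                n_draws=600,
                n_burn=200,
                thin=1,
                seed=7,
                time_varying_b=False,
                time_varying_a=False,
                time_varying_s=False,
            ),
        )
        # sampled paths constant over time (exact)
        np.testing.assert_array_equal(draws.b_path[:, 0, :], draws.b_path[:, -1, :])
        np.testing.assert_array_equal(
            draws.alpha_path[:, 0, :], draws.alpha_path[:, -1, :]
        )
        np.testing.assert_array_equal(
            draws.sigma_path[:, 0, :], draws.sigma_path[:, -1, :]
        )
        from statsmodels.tsa.api import VAR

        bols = VAR(y).fit(maxlags=1, trend="n").coefs[0]
        bmean = draws.b_path[:, 0, :].mean(0).reshape(m, m, order="F")
        bsd = draws.b_path[:, 0, :].std(0).reshape(m, m, order="F")
        assert np.all(np.abs(bmean - bols) < 3 * bsd)

    def test_volatility_level_recovered(self, small_dataset, small_fit):
        sig_hat = small_fit.sigma_path.mean(axis=(0, 1))
        sig_true = small_dataset.truth.sigma_path[1:].mean(axis=0)
        assert np.all(np.abs(sig_hat - sig_true) / sig_true < 0.5)

    def test_sign_switch_coefficient_path_recovered(self):
        """The posterior-mean uncertainty -> target coefficient keeps the
        correct sign on both sides of the switch at most time points."""
        ds = simulate_tvp_favar(sign_switch_preset(T=200, seed=1))
        dims = ModelDims(k=1, l=1, p=1, q=0, T=200)
        draws = run_gibbs(
            ds.y,
            dims,
            sampler=SamplerConfig(n_draws=1500, n_burn=500, thin=2, seed=101),
        )
        m = 3
        pos = (m - 1) * m + 1  # b_1t[target=1, epu=2], column-major
        bmean = draws.b_path[:, :, pos].mean(axis=0)
        true_b = ds.truth.b_path[1:, pos]
        assert np.mean(np.sign(bmean) == np.sign(true_b)) >= 0.8

    def test_two_step_with_panel_samples_loadings(self, panel_dataset):
        ds = panel_dataset
        X, _, _ = standardize(ds.panel.to_numpy())
        X = np.asarray(X)
        f, _ = extract_factors_pca(X, 2)
        y = np.hstack([f, ds.core.to_numpy(), ds.epu.to_numpy()[:, None]])
        dims = ModelDims(k=2, l=1, p=2, q=1, n=X.shape[1], T=60)
        draws = run_gibbs(
            y,
            dims,
            panel=X,
            sampler=SamplerConfig(n_draws=120, n_burn=60, thin=1, seed=5),
        )
        assert draws.loadings is not None
        assert draws.loadings.shape == (60, X.shape[1], dims.m)
        assert np.isfinite(draws.loadings).all()

    def test_joint_mode_factors_consistent_with_pca(self, panel_dataset):
        """With the idiosyncratic block held at truth, joint-mode
        posterior-mean factors reproduce the canonicalized PCA factors."""
        results = []
        for seed in (4, 5):
            ds = simulate_tvp_favar(
                ScenarioConfig(T=60, n=60, k=2, l=1, p=2, q=0, seed=seed)
            )
            X, _, sd = standardize(ds.panel.to_numpy())
            X = np.asarray(X)
            f_pca, _ = extract_factors_pca(X, 2)
            y = np.hstack([f_pca, ds.core.to_numpy(), ds.epu.to_numpy()[:, None]])
            ref = _identify_factors(
                f_pca, f_pca / f_pca.std(axis=0, ddof=1), observed=y[:, 2:]
            )
            dims = ModelDims(k=2, l=1, p=2, q=0, n=60, T=60)
            h_true = ds.truth.h_path - np.log(np.asarray(sd))[None, :]
            idio = IdiosyncraticModel(
                rho=np.zeros((60, 0)), h_path=h_true, q_h=0.0
            )
            draws = run_gibbs(
                y,
                dims,
                panel=X,
                fixed_idio=idio,
                sampler=SamplerConfig(
                    n_draws=400, n_burn=150, thin=1, seed=9, mode="joint"
                ),
            )
            fmean = draws.factor_path.mean(axis=0)
            for j in range(2):
                results.append(abs(np.corrcoef(fmean[:, j], ref[:, j])[0, 1]))
        assert min(results) >= 0.95


class TestDiagnostics:
    def test_geweke_null_calibrated(self):
        hits = 0
        for s in range(200):
            z = geweke_z(np.random.default_rng(1000 + s).standard_normal(5000))
            hits += abs(z) < 3
        assert hits / 200 >= 0.99

    def test_geweke_detects_mean_shift(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([np.zeros(2500), np.full(2500, 5.0)])
        x = x + 0.5 * rng.standard_normal(5000)
        assert abs(geweke_z(x)) > 5

    def test_geweke_degenerate_chain_flagged(self):
        assert np.isnan(geweke_z(np.ones(100)))

    def test_geweke_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.zeros(40))

    def test_if_iid_near_one(self):
        rng = np.random.default_rng(3)
        vals = [inefficiency_factor(rng.standard_normal(10000)) for _ in range(5)]
        assert all(0.7 < v < 1.5 for v in vals)

    def test_if_ar1_matches_windowed_closed_form(self):
        """Oracle: the tapered estimator targets 1 + 2 sum w_k phi^k at the
        configured bandwidth (the untruncated limit (1+phi)/(1-phi) is
        approached only as the bandwidth grows)."""
        phi, n = 0.9, 10000
        K = max(int(4 * (n / 100.0) ** 0.25), 1)
        target = 1 + 2 * (_parzen_weights(K) * phi ** np.arange(1, K + 1)).sum()
        rng = np.random.default_rng(4)
        ests = []
        for _ in range(10):
            x = np.zeros(n)
            e = rng.standard_normal(n)
            for t in range(1, n):
                x[t] = phi * x[t - 1] + e[t]
            ests.append(inefficiency_factor(x))
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - target) < 3 * se + 0.05

    def test_if_moderate_persistence_near_asymptotic_value(self):
        phi, n = 0.5, 10000
        rng = np.random.default_rng(5)
        x = np.zeros(n)
        e = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + e[t]
        assert abs(inefficiency_factor(x) - 3.0) < 0.6

    def test_if_short_chain_rejected(self):
        with pytest.raises(ValueError):
            inefficiency_factor(np.zeros(99))

    def test_posterior_summary_ordering_and_symmetry(self, small_fit):
        summ = posterior_summary(small_fit)
        for ps in summ.values():
            assert (ps.quantiles[0.05] <= ps.quantiles[0.5] + 1e-12).all()
            assert (ps.quantiles[0.5] <= ps.quantiles[0.95] + 1e-12).all()
        b = summ["b_path"]
        spread = b.quantiles[0.95] - b.quantiles[0.05]
        gap = np.abs(b.mean - b.quantiles[0.5])
        assert np.median(gap / (spread + 1e-12)) < 0.2

    def test_posterior_summary_needs_enough_draws(self, small_fit):
        import dataclasses

        few = dataclasses.replace(small_fit, b_path=small_fit.b_path[:20])
        with pytest.raises(ValueError):
            posterior_summary(few)
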