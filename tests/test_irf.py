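import numpy as np
import pytest

from svtvpfavar.irf import (
    IRFSurface,
    build_companion,
    export_surface,
    irf_path_at_time,
    irf_surface_from_draws,
    load_surface,
    structural_impact,
)


class TestCompanion:
    def test_single_lag_companion_is_coefficient_matrix(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=(3, 3))
        C = build_companion(b.ravel(order="F"), 3, 1)
        np.testing.assert_array_equal(C, b)

    def test_scalar_two_lag_hand_example(self):
        C = build_companion(np.array([0.5, 0.3]), 1, 2)
        np.testing.assert_array_equal(C, [[0.5, 0.3], [1.0, 0.0]])
        roots = np.roots([1.0, -0.5, -0.3])
        np.testing.assert_allclose(sorted(np.linalg.eigvals(C)), sorted(roots))

    def test_zero_coefficients_are_nilpotent(self):
        C = build_companion(np.zeros(4), 2, 1)
        assert (C == 0).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_companion(np.zeros(5), 2, 1)


class TestImpact:
    def test_identity_decomposition(self):
        imp = structural_impact(np.zeros(1), np.ones(2))
        np.testing.assert_array_equal(imp.matrix, np.eye(2))

    def test_two_by_two_hand_inversion(self):
        imp = structural_impact(np.array([0.5]), np.array([1.0, 2.0]))
        np.testing.assert_allclose(imp.matrix, [[1.0, 0.0], [-0.5, 2.0]])
        np.testing.assert_allclose(imp.omega, imp.matrix @ imp.matrix.T)

    def test_reconstruction_identity_on_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            m = rng.integers(2, 5)
            alpha = rng.normal(size=m * (m - 1) // 2)
            sigma = np.exp(rng.normal(size=m))
            imp = structural_impact(alpha, sigma)
            A = np.eye(m)
            pos = 0
            for i in range(1, m):
                A[i, :i] = alpha[pos : pos + i]
                pos += i
            omega = np.linalg.solve(A, np.diag(sigma**2)) @ np.linalg.inv(A).T
            assert np.max(np.abs(imp.omega - omega)) < 1e-10

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            structural_impact(np.zeros(1), np.array([1.0, 0.0]))


def shock_difference_oracle(b, alpha, sigma, shock_var, H, m, p):
    """Oracle: propagate the VAR with and without a one-time structural
    shock and difference the two paths."""
    imp = structural_impact(alpha, sigma).matrix
    blocks = [
        b[lag * m * m : (lag + 1) * m * m].reshape((m, m), order="F")
        for lag in range(p)
    ]
    def propagate(shock0):
        y = np.zeros((H + 1 + p, m))
        y[p] = shock0
        for t in range(p + 1, H + 1 + p):
            y[t] = sum(blocks[i] @ y[t - 1 - i] for i in range(p))
        return y[p:]
    return propagate(imp[:, shock_var]) - propagate(np.zeros(m))


class TestIRFPath:
    def test_horizon_zero_is_impact_column(self):
        rng = np.random.default_rng(2)
        m, p = 3, 2
        b = rng.normal(0, 0.1, m * m * p)
        alpha = rng.normal(size=3)
        sigma = np.exp(rng.normal(size=3))
        path = irf_path_at_time(b, alpha, sigma, 2, 6, m, p)
        np.testing.assert_allclose(
            path[0], structural_impact(alpha, sigma).matrix[:, 2], atol=1e-12
        )

    def test_scalar_geometric_closed_form(self):
        path = irf_path_at_time(
            np.array([0.5]), np.empty(0), np.array([1.0]), 0, 5, 1, 1, "unit"
        )
        np.testing.assert_allclose(path[:, 0], 0.5 ** np.arange(6))

    def test_matches_shock_difference_oracle(self):
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(100):
            m = int(rng.integers(2, 4))
            p = int(rng.integers(1, 3))
            while True:
                b = rng.normal(0, 0.25, m * m * p)
                C = build_companion(b, m, p)
                if np.max(np.abs(np.linalg.eigvals(C))) < 0.95:
                    break
            alpha = rng.normal(size=m * (m - 1) // 2)
            sigma = np.exp(rng.normal(0, 0.3, m))
            sv = int(rng.integers(0, m))
            H = 8
            got = irf_path_at_time(b, alpha, sigma, sv, H, m, p)
            want = shock_difference_oracle(b, alpha, sigma, sv, H, m, p)
            worst = max(worst, np.max(np.abs(got - want)))
        assert worst < 1e-10

    def test_fixed_coefficient_single_lag_closed_form(self):
        rng = np.random.default_rng(4)
        m = 3
        b = rng.normal(0, 0.2, (m, m))
        alpha = rng.normal(size=3)
        sigma = np.exp(rng.normal(size=m))
        col = structural_impact(alpha, sigma).matrix[:, 1]
        path = irf_path_at_time(b.ravel(order="F"), alpha, sigma, 1, 5, m, 1)
        for h in range(6):
            np.testing.assert_allclose(
                path[h], np.linalg.matrix_power(b, h) @ col, atol=1e-12
            )


class TestSurface:
    def test_constant_draws_give_time_constant_surface(self, small_fit):
        d = small_fit
        import dataclasses

        frozen = dataclasses.replace(
            d,
            b_path=np.repeat(d.b_path[:, :1, :], d.b_path.shape[1], axis=1),
            alpha_path=np.repeat(d.alpha_path[:, :1, :], d.alpha_path.shape[1], axis=1),
            sigma_path=np.repeat(d.sigma_path[:, :1, :], d.sigma_path.shape[1], axis=1),
        )
        surf = irf_surface_from_draws(frozen, shock_var=2, H=4)
        np.testing.assert_allclose(surf.q50[0], surf.q50[-1], atol=1e-12)

    def test_quantile_ordering_everywhere(self, small_fit):
        surf = irf_surface_from_draws(small_fit, shock_var=2, H=6)
        assert (surf.q05 <= surf.q50 + 1e-12).all()
        assert (surf.q50 <= surf.q95 + 1e-12).all()

    def test_export_shape_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        T, H, m = 74, 12, 5
        qs = np.sort(rng.normal(size=(3, T, H + 1, m)), axis=0)
        surf = IRFSurface(
            times=[f"t{t}" for t in range(T)],
            horizons=np.arange(H + 1),
            variable_names=[f"v{j}" for j in range(m)],
            q05=qs[0],
            q50=qs[1],
            q95=qs[2],
        )
        path = tmp_path / "surface.csv"
        export_surface(surf, path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1 + T * (H + 1) * m  # header + one row per cell
        back = load_surface(path)
        np.testing.assert_allclose(back.q05, surf.q05, atol=1e-12)
        np.testing.assert_allclose(back.q95, surf.q95, atol=1e-12)

    def test_empty_surface_writes_header_only(self, tmp_path):
        surf = IRFSurface(
            times=[],
            horizons=np.arange(0),
            variable_names=[],
            q05=np.zeros((0, 0, 0)),
            q50=np.zeros((0, 0, 0)),
            q95=np.zeros((0, 0, 0)),
        )
        path = tmp_path / "empty.csv"
        export_surface(surf, path)
        assert path.read_text().strip() == "quarter,horizon,variable,q05,q50,q95"

    def test_slice_consistent_with_surface(self, small_fit):
        surf = irf_surface_from_draws(small_fit, shock_var=2, H=4, times=None)
        sl = surf.slice_at(10)
        np.testing.assert_array_equal(sl.q50, surf.q50[10])
        lo, med, hi = sl.response(1)
        np.testing.assert_array_equal(med, surf.q50[10, :, 1])

    def test_plot_slice_runs(self, small_fit):
        surf = irf_surface_from_draws(small_fit, shock_var=2, H=4)
        ax = surf.plot_slice(surf.times[5], surf.variable_names[1])
        assert ax is not None
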