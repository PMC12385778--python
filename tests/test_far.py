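"""FAR kernel estimation and the sequential chi-squared order test."""

import numpy as np
import pytest

import denscar.far as far_mod
from denscar._linalg import quad_weights
from denscar.far import (OrderTestResult, default_far_dimension, far_order_test,
                         fit_far_kernels, select_order)
from denscar.splines import BSplineBasis


def fourier_curves(rng, T, grid, n_modes=5, scale=1.0):
    modes = np.array([np.sin(np.pi * j * grid) / j for j in range(1, n_modes + 1)])
    return scale * rng.normal(size=(T, n_modes)) @ modes


def noise_free_far1_series(rng, T, grid, segment=4):
    """Segments of exact operator iterates under gamma(s,u) = 0.2 u s, seeded
    with fresh rich curves: every within-segment transition is an exact,
    innovation-free regression row."""
    w = quad_weights(grid)
    modes = np.array([np.sin(np.pi * j * grid) for j in range(1, 7)]
                     + [np.cos(np.pi * j * grid) for j in range(4)])
    rows = []
    while len(rows) < T:
        x = (rng.normal(size=modes.shape[0]) / np.arange(1, modes.shape[0] + 1)) @ modes
        rows.append(x)
        for _ in range(segment - 1):
            x = 0.2 * grid * np.sum(grid * x * w)
            rows.append(x)
    return np.asarray(rows[:T])


class TestKernelFit:
    def test_zero_residuals_give_null_fit(self):
        grid = np.linspace(0.01, 0.99, 40)
        fit = fit_far_kernels(np.zeros((15, 40)), grid, 1)
        np.testing.assert_allclose(fit.mu, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.rho, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.innovations, 0.0, atol=1e-12)

    def test_equals_bruteforce_normal_equations(self, rng):
        """Tiny instance: build the regressor matrix by explicit loops and
        solve the normal equations directly."""
        grid = np.linspace(0.02, 0.98, 25)
        T, p = 14, 2
        resid = fourier_curves(rng, T, grid)
        basis = BSplineBasis.from_dimension(3, order=3)
        fit = fit_far_kernels(resid, grid, p, basis=basis)

        w = quad_weights(grid)
        Bu = basis.design(grid)
        N = basis.dimension
        rows, ys = [], []
        for t in range(p, T):
            for i, ui in enumerate(grid):
                row = []
                for l in range(1, p + 1):
                    for r in range(N):
                        for j in range(N):
                            c = np.sum(Bu[:, j] * resid[t - l] * w)
                            row.append(Bu[i, r] * c)
                rows.append(row)
                ys.append(resid[t, i])
        A = np.asarray(rows)
        mu_brute = np.linalg.solve(A.T @ A, A.T @ np.asarray(ys))
        np.testing.assert_allclose(fit.mu, mu_brute, atol=1e-8)

    def test_kernel_recovery_improves_with_length(self):
        grid = np.linspace(0, 1, 101)
        truth = 0.2 * np.outer(grid, grid)
        errs = []
        for T in (500, 2000):
            rng = np.random.default_rng(7)
            eps = noise_free_far1_series(rng, T, grid)
            fit = fit_far_kernels(eps, grid, 1)
            errs.append(np.abs(fit.kernel_surface(1) - truth).max())
        assert errs[1] < errs[0]
        assert errs[1] < 0.02

    def test_rank_deficient_features_trigger_ridge_warning(self, rng):
        grid = np.linspace(0.01, 0.99, 60)
        # curves confined to a 2-dim space cannot identify a 4x4 kernel basis
        resid = fourier_curves(rng, 40, grid, n_modes=2)
        with pytest.warns(RuntimeWarning, match="condition number"):
            fit_far_kernels(resid, grid, 1)

    def test_innovation_whiteness_after_correct_fit(self):
        """Lag-1 inner products of fitted innovations are centered near 0."""
        grid = np.linspace(0, 1, 51)
        rng = np.random.default_rng(3)
        from denscar.simulate import gen_far_errors
        innov = fourier_curves(rng, 1050, grid, scale=0.1)
        eps = gen_far_errors(1000, [lambda s, u: 0.2 * u * s], innov, grid, 50)
        fit = fit_far_kernels(eps, grid, 1)
        w = quad_weights(grid)
        e = fit.innovations
        ips = np.einsum("tg,g,tg->t", e[1:], w, e[:-1])
        se = ips.std(ddof=1) / np.sqrt(ips.size)
        assert abs(ips.mean()) < 3 * se + 1e-12

    def test_default_dimension_rule(self):
        assert default_far_dimension(100) == 4
        assert default_far_dimension(100000) == 10

    def test_short_series_rejected(self):
        grid = np.linspace(0.01, 0.99, 10)
        with pytest.raises(ValueError):
            fit_far_kernels(np.zeros((3, 10)), grid, 3)


class TestOrderTest:
    def test_statistic_nonnegative_pvalue_valid(self, rng):
        grid = np.linspace(0.01, 0.99, 30)
        res = far_order_test(fourier_curves(rng, 60, grid), grid, 0)
        assert res.statistic >= 0
        assert 0.0 <= res.p_value <= 1.0
        assert res.df == res.q_pi * res.q_star

    def test_last_segment_gram_is_identity_for_single_segment(self, rng):
        """With p_null=0 the predictor has one segment, so every eigenvalue
        of the last-segment Gram equals 1 and q* = q_eta."""
        grid = np.linspace(0.01, 0.99, 30)
        res = far_order_test(fourier_curves(rng, 80, grid), grid, 0)
        assert res.q_star == res.q_eta

    def test_detects_strong_far1_dependence(self):
        """A heavily dependent FAR(1) process is rejected for H0: iid."""
        grid = np.linspace(0, 1, 41)
        rng = np.random.default_rng(5)
        from denscar.simulate import gen_far_errors
        innov = fourier_curves(rng, 350, grid, scale=0.3)
        strong = lambda s, u: 1.6 * np.sin(np.pi * u) * np.sin(np.pi * s)
        eps = gen_far_errors(300, [strong], innov, grid, 50)
        res = far_order_test(eps, grid, 0)
        assert res.p_value < 0.01

    def test_size_under_iid_is_near_nominal(self):
        rejs = []
        grid = np.linspace(0.01, 0.99, 31)
        for r in range(100):
            rng = np.random.default_rng([41, r])
            res = far_order_test(fourier_curves(rng, 300, grid), grid, 0)
            rejs.append(res.p_value < 0.05)
        assert 0.0 <= np.mean(rejs) <= 0.12

    def test_too_short_series_rejected(self, rng):
        grid = np.linspace(0.01, 0.99, 10)
        with pytest.raises(ValueError):
            far_order_test(fourier_curves(rng, 8, grid), grid, 0)

    def test_segment_convention_option(self, rng):
        grid = np.linspace(0.01, 0.99, 30)
        curves = fourier_curves(rng, 80, grid)
        r1 = far_order_test(curves, grid, 1, segments="p_plus_1")
        r2 = far_order_test(curves, grid, 1, segments="p")
        assert isinstance(r1, OrderTestResult) and isinstance(r2, OrderTestResult)
        assert r1.statistic != r2.statistic


class TestSelectOrder:
    def test_stop_rule_applies_pvalue_trail(self, rng, monkeypatch):
        trail = {0: 0.001, 1: 0.30, 2: 0.9}

        def fake_test(resid, grid_u, p_null, **kw):
            return OrderTestResult(p_null=p_null, statistic=1.0, df=1,
                                   p_value=trail[p_null], q_eta=1, q_pi=1, q_star=1)

        monkeypatch.setattr(far_mod, "far_order_test", fake_test)
        grid = np.linspace(0.01, 0.99, 20)
        p_hat, results = select_order(fourier_curves(rng, 40, grid), grid)
        assert p_hat == 1
        assert [r.p_null for r in results] == [0, 1]

    def test_all_rejected_returns_pmax_with_warning(self, rng, monkeypatch):
        def fake_test(resid, grid_u, p_null, **kw):
            return OrderTestResult(p_null=p_null, statistic=99.0, df=1,
                                   p_value=0.0, q_eta=1, q_pi=1, q_star=1)

        monkeypatch.setattr(far_mod, "far_order_test", fake_test)
        grid = np.linspace(0.01, 0.99, 20)
        with pytest.warns(RuntimeWarning, match="p_max"):
            p_hat, _ = select_order(fourier_curves(rng, 40, grid), grid, p_max=2)
        assert p_hat == 2

    def test_iid_curves_mostly_select_zero(self):
        grid = np.linspace(0.01, 0.99, 31)
        picks = []
        for r in range(30):
            rng = np.random.default_rng([17, r])
            p_hat, _ = select_order(fourier_curves(rng, 250, grid), grid, p_max=2)
            picks.append(p_hat)
        assert np.mean(np.asarray(picks) == 0) >= 0.8
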