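"""Three-step varying-coefficient estimation: least squares, correction, RMSE,
bootstrap."""

import numpy as np
import pytest

from denscar.far import FARFit, fit_far_kernels
from denscar.lqd import default_level_grid
from denscar.splines import BSplineBasis, TensorSplineBasis
from denscar.vca import (DensityVCAFAR, compute_residuals, correct_response,
                         fit_initial, rmse_surface)


def _toy_problem(rng, T=40, n_u=30, k=2):
    grid_u = default_level_grid(n_u)
    Z = np.column_stack([rng.normal(size=T), rng.normal(0, 0.5, T)])
    X = rng.uniform(0.02, 0.98, (T, k))
    spec = TensorSplineBasis.default(n=n_u, T=T, k=k)
    spec.normalize_x(X)
    return grid_u, Z, X, spec


class TestInitialFit:
    def test_exact_recovery_of_span_member(self, rng):
        grid_u, Z, X, spec = _toy_problem(rng)
        lam0 = rng.normal(size=spec.n_coef)
        F = (spec.full_design(grid_u, X, Z) @ lam0).reshape(40, 30)
        coef, fitted, _ = fit_initial(F, Z, X, spec, grid_u)
        np.testing.assert_allclose(coef, lam0, atol=1e-8)
        np.testing.assert_allclose(fitted, F, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        grid_u, Z, X, spec = _toy_problem(rng)
        F = rng.normal(size=(40, 30))
        coef, fitted, _ = fit_initial(F, Z, X, spec, grid_u)
        B = spec.full_design(grid_u, X, Z)
        r = F.ravel() - B @ coef
        scale = np.abs(B.T @ F.ravel()).max()
        assert np.abs(B.T @ r).max() < 1e-6 * max(scale, 1.0)

    def test_equals_bruteforce_normal_equations(self, rng):
        grid_u, Z, X, spec = _toy_problem(rng, T=8, n_u=20)
        F = rng.normal(size=(8, 20))
        coef, _, _ = fit_initial(F, Z, X, spec, grid_u)
        B = spec.full_design(grid_u, X, Z)
        brute = np.linalg.solve(B.T @ B, B.T @ F.ravel())
        np.testing.assert_allclose(coef, brute, atol=1e-8)

    def test_constant_model_fits_sample_mean(self, rng):
        """k=1, z=1, single constant basis: the LS fit is the grand mean."""
        T, n_u = 12, 15
        grid_u = default_level_grid(n_u)
        F = rng.normal(1.3, 0.2, size=(T, n_u))
        model = DensityVCAFAR(order=0, spline_order=1, n_basis_u=1, n_basis_x=1)
        model.fit(F, np.ones((T, 1)), rng.uniform(size=(T, 1)), grid_u)
        np.testing.assert_allclose(model.fitted_, F.mean(), atol=1e-10)

    def test_underdetermined_design_rejected(self, rng):
        grid_u, Z, X, spec = _toy_problem(rng, T=2, n_u=3)
        with pytest.raises(ValueError):
            fit_initial(rng.normal(size=(2, 3)), Z, X, spec, grid_u)


class TestResidualsAndCorrection:
    def test_residuals_identity(self, rng):
        F = rng.normal(size=(5, 7))
        fitted = rng.normal(size=(5, 7))
        np.testing.assert_array_equal(compute_residuals(F, fitted), F - fitted)

    def test_zero_kernels_leave_response_unchanged(self, rng):
        grid_u = default_level_grid(25)
        basis = BSplineBasis.from_dimension(4)
        resid = rng.normal(size=(10, 25))
        far = FARFit(p=1, basis=basis, grid_u=grid_u,
                     mu=np.zeros(16), rho=np.zeros((9, 25)),
                     innovations=resid[1:])
        F = rng.normal(size=(10, 25))
        np.testing.assert_allclose(correct_response(F, far, resid), F[1:])

    def test_constant_kernel_subtracts_constant(self):
        """gamma(s,u)=1 with eps_{t-1} = c subtracts exactly c."""
        grid_u = default_level_grid(50)
        basis = BSplineBasis.from_dimension(4)
        mu = np.ones(16)  # sum_{r,j} B_r(u) B_j(s) = 1 by partition of unity
        c = 0.7
        resid = np.full((4, 50), c)
        far = FARFit(p=1, basis=basis, grid_u=grid_u, mu=mu,
                     rho=np.zeros((3, 50)), innovations=np.zeros((3, 50)))
        F = np.zeros((4, 50))
        out = correct_response(F, far, resid)
        np.testing.assert_allclose(out, -c, atol=1e-10)

    def test_quadrature_matches_fine_riemann_sum(self, rng):
        """The serial-component integral agrees with a refined-grid oracle."""
        grid_u = default_level_grid(2000)
        basis = BSplineBasis.from_dimension(5)
        mu = rng.normal(size=25)
        far = FARFit(p=1, basis=basis, grid_u=grid_u, mu=mu,
                     rho=np.zeros((1, 2000)), innovations=np.zeros((1, 2000)))
        curve = np.sin(2 * np.pi * grid_u) + 0.3 * grid_u
        rho = far.serial_component(np.vstack([curve, curve]))[0]
        fine = np.linspace(0, 1, 20001)
        curve_fine = np.sin(2 * np.pi * fine) + 0.3 * fine
        gam = far.kernel_surface(1, s=fine, u=grid_u)   # rows s, cols u
        oracle = np.trapezoid(gam * curve_fine[:, None], fine, axis=0)
        np.testing.assert_allclose(rho, oracle, atol=1e-6)


class TestSurfaceAndRMSE:
    def test_zero_coefficients_zero_surface(self, rng):
        grid_u, Z, X, _ = _toy_problem(rng)
        F = np.zeros((40, 30))
        m = DensityVCAFAR(order=0).fit(F, Z, X, grid_u)
        assert m.evaluate_surface(0, 0.3, 0.6) == pytest.approx(0.0, abs=1e-10)

    def test_linearity_in_coefficients(self, rng):
        grid_u, Z, X, _ = _toy_problem(rng)
        F = rng.normal(size=(40, 30))
        m = DensityVCAFAR(order=0).fit(F, Z, X, grid_u)
        v1 = m.evaluate_surface(1, 0.4, 0.7)
        m.coef_ = 2 * m.coef_
        assert m.evaluate_surface(1, 0.4, 0.7) == pytest.approx(2 * v1)

    def test_surface_matches_bruteforce_sum(self, rng):
        grid_u, Z, X, _ = _toy_problem(rng)
        F = rng.normal(size=(40, 30))
        m = DensityVCAFAR(order=0).fit(F, Z, X, grid_u)
        spec = m.basis_
        sl = spec.coef_slices()[0]
        lam = m.coef_[sl].reshape(spec.basis_u.dimension, spec.dims[0])
        for u0, x0 in rng.uniform(0.02, 0.98, (20, 2)):
            acc = 0.0
            for r in range(spec.basis_u.dimension):
                for j in range(spec.dims[0]):
                    acc += (lam[r, j] * spec.basis_u.design([u0])[0, r]
                            * spec.basis_x[0].design([x0])[0, j])
            assert m.evaluate_surface(0, u0, x0) == pytest.approx(acc, abs=1e-10)

    def test_rmse_zero_iff_exact(self):
        grid_u = default_level_grid(10)
        x = np.array([0.2, 0.8, 0.5])
        g = lambda u, xv: np.sin(u) * xv
        assert rmse_surface(g, g, x, grid_u) == 0.0

    def test_rmse_constant_offset(self):
        grid_u = default_level_grid(10)
        x = np.array([0.2, 0.8])
        g = lambda u, xv: u * 0.0
        g2 = lambda u, xv: u * 0.0 + 0.37
        assert rmse_surface(g2, g, x, grid_u) == pytest.approx(0.37)

    def test_rmse_matches_double_loop(self, rng):
        grid_u = np.array([0.2, 0.4, 0.6, 0.8])
        x = rng.uniform(size=3)
        est = lambda u, xv: u**2 + xv
        tru = lambda u, xv: u * xv
        total = 0.0
        for xt in x:
            inner = np.mean([(ui**2 + xt - ui * xt) ** 2 for ui in grid_u])
            total += np.sqrt(inner)
        assert rmse_surface(est, tru, x, grid_u) == pytest.approx(total / 3)


class TestThreeStep:
    def test_improved_equals_initial_without_serial_structure(self, rng):
        """Noise-free responses in the spline span: residuals vanish, the FAR
        fit is null, and the improved fit reproduces the initial one."""
        grid_u, Z, X, spec = _toy_problem(rng)
        lam0 = rng.normal(size=spec.n_coef)
        F = (spec.full_design(grid_u, X, Z) @ lam0).reshape(40, 30)
        m = DensityVCAFAR(order=1).fit(F, Z, X, grid_u)
        np.testing.assert_allclose(m.coef_, m.coef_initial_, atol=1e-8)
        assert np.abs(m.far_.rho).max() < 1e-8

    def test_order_zero_skips_correction(self, rng):
        grid_u, Z, X, _ = _toy_problem(rng)
        F = rng.normal(size=(40, 30))
        m = DensityVCAFAR(order=0).fit(F, Z, X, grid_u)
        assert m.far_ is None
        assert m.order_ == 0
        np.testing.assert_array_equal(m.coef_, m.coef_initial_)

    def test_predict_reproduces_fitted(self, rng):
        grid_u, Z, X, _ = _toy_problem(rng)
        F = rng.normal(size=(40, 30))
        m = DensityVCAFAR(order=0).fit(F, Z, X, grid_u)
        np.testing.assert_allclose(m.predict(Z, X), m.fitted_, atol=1e-10)

    def test_input_validation(self, rng):
        grid_u, Z, X, _ = _toy_problem(rng)
        with pytest.raises(ValueError):
            DensityVCAFAR().fit(np.full((40, 30), np.nan), Z, X, grid_u)
        with pytest.raises(ValueError):
            DensityVCAFAR().fit(rng.normal(size=(40, 30)), Z, X + 5.0, grid_u)

    def test_sklearn_param_interface(self):
        m = DensityVCAFAR(alpha=0.01)
        assert m.get_params()["alpha"] == 0.01
        m.set_params(max_order=2)
        assert m.max_order == 2


class TestBootstrap:
    def _fitted_model(self, rng, T=30, n_u=20, exact=False):
        grid_u, Z, X, spec = _toy_problem(rng, T=T, n_u=n_u)
        Z, X = Z[:T], X[:T]
        lam0 = rng.normal(size=spec.n_coef)
        F = (spec.full_design(grid_u, X, Z) @ lam0).reshape(T, n_u)
        if not exact:
            F = F + rng.normal(0, 0.1, F.shape)
        return DensityVCAFAR(order=0).fit(F, Z, X, grid_u)

    def test_degenerate_residuals_give_zero_se(self, rng):
        m = self._fitted_model(rng, exact=True)
        boot = m.bootstrap_inference(n_boot=5, seed=0,
                                     eval_u=np.array([0.3, 0.7]),
                                     eval_x=np.array([0.4]))
        np.testing.assert_allclose(boot["se"], 0.0, atol=1e-7)

    def test_same_seed_reproduces_ci(self, rng):
        m = self._fitted_model(rng)
        b1 = m.bootstrap_inference(n_boot=8, seed=11,
                                   eval_u=np.array([0.5]), eval_x=np.array([0.5]))
        b2 = m.bootstrap_inference(n_boot=8, seed=11,
                                   eval_u=np.array([0.5]), eval_x=np.array([0.5]))
        np.testing.assert_array_equal(b1["ci_lower"], b2["ci_lower"])
        np.testing.assert_array_equal(b1["ci_upper"], b2["ci_upper"])

    def test_requires_two_replications(self, rng):
        m = self._fitted_model(rng)
        with pytest.raises(ValueError):
            m.bootstrap_inference(n_boot=1)

    def test_se_shrinks_with_series_length(self):
        """Pointwise SEs scale roughly like 1/sqrt(T)."""
        ses = []
        for T in (60, 240):
            rng = np.random.default_rng(99)
            grid_u = default_level_grid(20)
            Z = np.column_stack([rng.normal(size=T), rng.normal(0, 0.5, T)])
            X = rng.uniform(0.02, 0.98, (T, 2))
            spec = TensorSplineBasis.default(n=20, T=T, k=2)
            lam0 = rng.normal(size=spec.n_coef)
            F = (spec.full_design(grid_u, X, Z) @ lam0).reshape(T, 20)
            F = F + rng.normal(0, 0.3, F.shape)
            m = DensityVCAFAR(order=0, n_basis_u=spec.basis_u.dimension,
                              n_basis_x=spec.dims[0]).fit(F, Z, X, grid_u)
            boot = m.bootstrap_inference(n_boot=60, seed=5,
                                         eval_u=np.linspace(0.2, 0.8, 5),
                                         eval_x=np.linspace(0.2, 0.8, 5))
            ses.append(boot["se"].mean())
        ratio = ses[0] / ses[1]
        assert 1.4 < ratio < 2.8
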