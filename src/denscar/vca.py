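"""Varying-coefficient additive regression for LQD-transformed density responses.

The model for the transformed response curves f_t(u) = Psi(d_t)(u) is

    f_t(u) = sum_{m=1..k} z_{t,m} g_m(u, x_{t,m}) + eps_t(u),

with bivariate coefficient surfaces g_m and an error process eps_t that may
follow a functional auto-regression of order p.  Estimation proceeds in
three steps: (1) a tensor-product B-spline least-squares fit ignoring the
error structure, (2) estimation of the FAR operator (and, if requested, its
order by sequential testing) from the step-1 residuals, and (3) a refit on
the serially corrected response f_t - sum_l int gamma_hat_l(s, u)
eps_hat_{t-l}(s) ds, which discards the first p time points.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._linalg import lstsq_ridge
from .far import FARFit, default_far_dimension, fit_far_kernels, select_order
from .lqd import default_level_grid
from .splines import BSplineBasis, TensorSplineBasis

__all__ = [
    "DensityVCAFAR",
    "fit_initial",
    "compute_residuals",
    "correct_response",
    "rmse_surface",
]


def fit_initial(F: np.ndarray, Z: np.ndarray, X: np.ndarray,
                basis: TensorSplineBasis, grid_u: np.ndarray,
                cond_threshold: float = 1e10, ridge: float = 1e-8):
    """Global least-squares fit of all additive components jointly.

    Returns (coefficient vector, fitted T x n_u matrix, condition number).
    """
    B = basis.full_design(grid_u, X, Z)
    if B.shape[0] <= B.shape[1]:
        raise ValueError("design has fewer rows than columns; enlarge T*n_u or shrink the basis")
    coef, cond = lstsq_ridge(B, F.ravel(), cond_threshold, ridge)
    fitted = (B @ coef).reshape(F.shape)
    return coef, fitted, cond


def compute_residuals(F: np.ndarray, fitted: np.ndarray) -> np.ndarray:
    """eps_tilde_t(u_i) = f_t(u_i) - fitted_t(u_i)."""
    return np.asarray(F, dtype=float) - np.asarray(fitted, dtype=float)


def correct_response(F: np.ndarray, far: FARFit, resid: np.ndarray) -> np.ndarray:
    """Adjusted response f_t(u) - sum_l int gamma_hat_l(s,u) eps_hat_{t-l}(s) ds.

    Output rows correspond to t = p+1..T (the first p points are dropped).
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if far.p >= F.shape[0]:
        raise ValueError("FAR order is not smaller than the series length")
    return F[far.p:] - far.serial_component(resid)


def rmse_surface(estimate, truth, x_values, grid_u) -> float:
    """Root mean squared error of a surface along the observed design.

    RMSE = (1/T) sum_t sqrt( (1/n) sum_i (est(u_i, x_t) - true(u_i, x_t))^2 ),
    where both callables take paired arrays (u, x).
    """
    grid_u = np.asarray(grid_u, dtype=float)
    x_values = np.atleast_1d(np.asarray(x_values, dtype=float))
    total = 0.0
    for x_t in x_values:
        xv = np.full_like(grid_u, x_t)
        diff = np.asarray(estimate(grid_u, xv), dtype=float) - \
            np.asarray(truth(grid_u, xv), dtype=float)
        total += float(np.sqrt(np.mean(diff**2)))
    return total / x_values.size


class DensityVCAFAR(BaseEstimator):
    """Varying-coefficient additive model with FAR errors for LQD curves.

    Parameters
    ----------
    order : "auto" or int
        FAR order of the error process.  "auto" selects it by the sequential
        chi-squared test at level ``alpha``; an integer fixes it (0 disables
        the correction and the improved fit equals the initial fit).
    alpha : float
        Level of the sequential order test.
    max_order : int
        Largest order considered by the sequential test.
    n_basis_u, n_basis_x : int or None
        Tensor-spline dimensions per margin; None uses the
        max(order, (n*T)**(1/6)) default.
    far_basis_dim : int or None
        Per-margin spline dimension for the FAR kernel surfaces; None uses
        max(4, T**(1/5)).
    q_eta, q_pi : int or None
        FPCA dimensions in the order test; None retains the smallest number
        of components explaining ``var_frac`` of variance, capped at
        ``max_fpca_dim``.

    Attributes (after fit)
    ----------------------
    coef_initial_, coef_ : spline coefficient vectors of the initial and
        improved fits; basis_ : the TensorSplineBasis; order_ : the FAR order
        used; far_ : FARFit or None; residuals_, innovations_ : curve
        matrices; order_trail_ : list of OrderTestResult from the sequential
        test (when order="auto").
    """

    def __init__(self, order="auto", alpha=0.05, max_order=4, spline_order=4,
                 n_basis_u=None, n_basis_x=None, rate_constant=1.0,
                 knot_rule="uniform", far_basis_dim=None,
                 q_eta=None, q_pi=None, var_frac=0.9, max_fpca_dim=5,
                 z_threshold=0.9, cond_threshold=1e10, ridge=1e-8):
        self.order = order
        self.alpha = alpha
        self.max_order = max_order
        self.spline_order = spline_order
        self.n_basis_u = n_basis_u
        self.n_basis_x = n_basis_x
        self.rate_constant = rate_constant
        self.knot_rule = knot_rule
        self.far_basis_dim = far_basis_dim
        self.q_eta = q_eta
        self.q_pi = q_pi
        self.var_frac = var_frac
        self.max_fpca_dim = max_fpca_dim
        self.z_threshold = z_threshold
        self.cond_threshold = cond_threshold
        self.ridge = ridge

    # ------------------------------------------------------------------ fit
    def fit(self, F, Z, X, grid_u=None):
        """Three-step fit on LQD curves F (T x n_u) with covariates Z, X (T x k)."""
        F = np.atleast_2d(np.asarray(F, dtype=float))
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        T, n_u = F.shape
        if Z.shape[0] != T or X.shape != Z.shape:
            raise ValueError("F, Z, X must share the time dimension and Z, X the shape")
        if not (np.all(np.isfinite(F)) and np.all(np.isfinite(Z)) and np.all(np.isfinite(X))):
            raise ValueError("non-finite values in the inputs")
        if np.any(X < 0) or np.any(X > 1):
            raise ValueError("index covariates X must lie in [0, 1]")
        grid_u = default_level_grid(n_u) if grid_u is None else np.asarray(grid_u, dtype=float)

        basis = TensorSplineBasis.default(
            n=n_u, T=T, k=Z.shape[1], order=self.spline_order,
            rate_constant=self.rate_constant, N0=self.n_basis_u, Nm=self.n_basis_x,
            knot_rule=self.knot_rule, X=X)
        basis.normalize_x(X)

        coef0, fitted0, cond0 = fit_initial(F, Z, X, basis, grid_u,
                                            self.cond_threshold, self.ridge)
        resid = compute_residuals(F, fitted0)

        order_trail = None
        if self.order == "auto":
            p_hat, order_trail = select_order(
                resid, grid_u, alpha=self.alpha, p_max=self.max_order,
                q_eta=self.q_eta, q_pi=self.q_pi, var_frac=self.var_frac,
                max_dim=self.max_fpca_dim, z_threshold=self.z_threshold)
        else:
            p_hat = int(self.order)
            if p_hat < 0:
                raise ValueError("order must be >= 0")

        if p_hat == 0:
            far = None
            coef1, fitted1, cond1 = coef0, fitted0, cond0
            innovations = resid
        else:
            dim = self.far_basis_dim or default_far_dimension(T)
            far = fit_far_kernels(resid, grid_u, p_hat,
                                  BSplineBasis.from_dimension(dim, self.spline_order),
                                  self.cond_threshold, self.ridge)
            F_corr = correct_response(F, far, resid)
            coef1, _, cond1 = fit_initial(F_corr, Z[p_hat:], X[p_hat:], basis, grid_u,
                                          self.cond_threshold, self.ridge)
            fitted1 = (basis.full_design(grid_u, X, Z) @ coef1).reshape(T, n_u)
            innovations = far.innovations

        self.basis_ = basis
        self.grid_u_ = grid_u
        self.coef_initial_ = coef0
        self.coef_ = coef1
        self.fitted_initial_ = fitted0
        self.fitted_ = fitted1
        self.residuals_ = resid
        self.innovations_ = innovations
        self.order_ = p_hat
        self.order_trail_ = order_trail
        self.far_ = far
        self.condition_ = {"initial": cond0, "improved": cond1}
        self._Z, self._X, self._F = Z, X, F
        return self

    # ------------------------------------------------------------- surfaces
    def evaluate_surface(self, m: int, u, x, stage: str = "improved") -> np.ndarray:
        """g_hat_m evaluated at paired (u, x) points in [0, 1]^2."""
        coef = {"improved": self.coef_, "initial": self.coef_initial_}[stage]
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(u_arr < 0) or np.any(u_arr > 1) or np.any(x_arr < 0) or np.any(x_arr > 1):
            raise ValueError("surface evaluation points must lie in [0, 1]^2")
        sl = self.basis_.coef_slices()[m]
        out = self.basis_.surface(m, coef[sl], u_arr, x_arr)
        return out if np.ndim(u) or np.ndim(x) else float(out[0])

    def predict(self, Z, X, stage: str = "improved") -> np.ndarray:
        """Fitted mean curves sum_m z_m g_hat_m(u_i, x_m) on the fit grid."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        coef = {"improved": self.coef_, "initial": self.coef_initial_}[stage]
        B = self.basis_.full_design(self.grid_u_, X, Z)
        return (B @ coef).reshape(Z.shape[0], self.grid_u_.size)

    # ------------------------------------------------------------ bootstrap
    def bootstrap_inference(self, n_boot: int = 500, seed=None,
                            eval_u=None, eval_x=None) -> dict:
        """Residual-based bootstrap for pointwise SEs and 95% CIs.

        Innovation curves are resampled with replacement, the FAR recursion
        rebuilds bootstrap error curves (initialized at resampled residual
        curves), bootstrap responses add these to the improved-stage fitted
        values, and the full three-step fit is repeated with the order fixed
        at the estimate.  Returns per-component SE and percentile CI arrays
        on the (eval_u, eval_x) grid, plus the grids.
        """
        if n_boot < 2:
            raise ValueError("need at least 2 bootstrap replications")
        rng = np.random.default_rng(seed)
        T, n_u = self._F.shape
        p = self.order_
        eval_u = np.linspace(0.05, 0.95, 19) if eval_u is None else np.asarray(eval_u)
        eval_x = np.linspace(0.05, 0.95, 19) if eval_x is None else np.asarray(eval_x)
        UU, XX = np.meshgrid(eval_u, eval_x, indexing="ij")

        k = self._Z.shape[1]
        surfaces = np.empty((n_boot, k, eval_u.size, eval_x.size))
        refit_params = self.get_params()
        refit_params["order"] = p
        for b in range(n_boot):
            eps_star = np.empty((T, n_u))
            if p == 0:
                eps_star = self.residuals_[rng.integers(0, T, size=T)]
            else:
                init_idx = rng.integers(0, self.residuals_.shape[0], size=p)
                eps_star[:p] = self.residuals_[init_idx]
                innov_idx = rng.integers(0, self.innovations_.shape[0], size=T - p)
                for t in range(p, T):
                    rho_t = self.far_.serial_component(eps_star[t - p:t + 1])[-1]
                    eps_star[t] = rho_t + self.innovations_[innov_idx[t - p]]
            F_star = self.fitted_ + eps_star
            model = DensityVCAFAR(**refit_params)
            model.fit(F_star, self._Z, self._X, self.grid_u_)
            for m in range(k):
                surfaces[b, m] = model.evaluate_surface(
                    m, UU.ravel(), XX.ravel()).reshape(UU.shape)

        se = surfaces.std(axis=0, ddof=1)
        lo = np.percentile(surfaces, 2.5, axis=0)
        hi = np.percentile(surfaces, 97.5, axis=0)
        return {"eval_u": eval_u, "eval_x": eval_x, "se": se,
                "ci_lower": lo, "ci_upper": hi, "n_boot": n_boot}
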