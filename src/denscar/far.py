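"""Functional auto-regressive (FAR) error processes.

Residual curves from the varying-coefficient fit may be serially dependent:
an order-p FAR process writes each curve as integral-kernel transforms of the
p preceding curves plus an i.i.d. innovation,

    eps_t(u) = sum_{l=1..p} int gamma_l(s, u) eps_{t-l}(s) ds + e_t(u).

The kernels gamma_l are expanded in a tensor-product B-spline basis and fit
by least squares.  The order p is chosen by a sequential chi-squared test
(nested null FAR(p) vs FAR(p+1)): the lagged curves are stacked into a single
predictor curve on [0, 1] split into p+1 segments, the full functional linear
regression is estimated by FPCA projection, and the coefficient mass that
eigen-directions concentrated on the *last* segment carry is compared to a
chi-squared reference.  Testing starts at p = 0 (i.i.d.) and stops at the
first non-rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._linalg import lstsq_ridge, quad_weights
from .splines import BSplineBasis

__all__ = [
    "FARFit",
    "OrderTestResult",
    "default_far_dimension",
    "fit_far_kernels",
    "far_order_test",
    "select_order",
]


def default_far_dimension(T: int) -> int:
    """Per-margin spline dimension for the FAR kernel surfaces: max(4, T**(1/5))."""
    return max(4, int(round(float(T) ** 0.2)))


@dataclass
class FARFit:
    """Fitted FAR(p) operator on residual curves.

    ``mu`` holds the p * N^2 tensor-spline coefficients (lag-major, then
    (r, j) with j fastest); ``rho`` the fitted serial component for
    t = p+1..T and ``innovations`` the centered innovation curves
    e_hat_t = eps_t - rho_t.
    """

    p: int
    basis: BSplineBasis
    grid_u: np.ndarray
    mu: np.ndarray
    rho: np.ndarray
    innovations: np.ndarray
    condition: float = np.nan
    _Bu: np.ndarray = field(init=False, repr=False)
    _wq: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._Bu = self.basis.design(self.grid_u)
        self._wq = quad_weights(self.grid_u)

    @property
    def mu_matrices(self) -> np.ndarray:
        """mu reshaped as (p, N, N) with [l, r, j] indexing."""
        N = self.basis.dimension
        return self.mu.reshape(self.p, N, N)

    def features(self, curves: np.ndarray) -> np.ndarray:
        """c[t, j] = int B_j(s) curve_t(s) ds by quadrature."""
        return np.atleast_2d(curves) @ (self._Bu * self._wq[:, None])

    def serial_component(self, curves: np.ndarray) -> np.ndarray:
        """rho_t(u_i) for t = p..len(curves)-1 given the preceding curves.

        Row t-p of the output is sum_l int gamma_hat_l(s, u) curve_{t-l}(s) ds.
        """
        curves = np.atleast_2d(curves)
        if curves.shape[0] <= self.p:
            raise ValueError("need more than p curves to form the serial component")
        c = self.features(curves)
        M = self.mu_matrices
        out = np.zeros((curves.shape[0] - self.p, self.grid_u.size))
        for l in range(1, self.p + 1):
            out += (self._Bu @ M[l - 1] @ c[self.p - l:curves.shape[0] - l].T).T
        return out

    def kernel_surface(self, l: int, s=None, u=None) -> np.ndarray:
        """gamma_hat_l evaluated on a (s, u) grid; defaults to the fit grid."""
        if not 1 <= l <= self.p:
            raise IndexError(f"lag {l} outside 1..{self.p}")
        s = self.grid_u if s is None else np.asarray(s, dtype=float)
        u = self.grid_u if u is None else np.asarray(u, dtype=float)
        Bs = self.basis.design(s)
        Bu = self.basis.design(u)
        # gamma_l(s, u) = sum_{r,j} mu[r,j,l] B_r(u) B_j(s); rows index s, cols u
        return Bs @ self.mu_matrices[l - 1].T @ Bu.T


def fit_far_kernels(resid: np.ndarray, grid_u: np.ndarray, p: int,
                    basis: BSplineBasis | None = None,
                    cond_threshold: float = 1e10, ridge: float = 1e-8) -> FARFit:
    """Least-squares tensor-spline fit of the FAR(p) kernel operators.

    The regressor for coefficient mu[r, j, l] at point (t, u_i) is
    B_r(u_i) * int B_j(s) eps_{t-l}(s) ds, with the integral computed by
    quadrature on the residual grid.
    """
    resid = np.atleast_2d(np.asarray(resid, dtype=float))
    grid_u = np.asarray(grid_u, dtype=float)
    T, n_u = resid.shape
    if p < 1:
        raise ValueError("FAR order must be >= 1 for kernel fitting")
    if T - p < 2:
        raise ValueError("insufficient series length for the requested order")
    if basis is None:
        basis = BSplineBasis.from_dimension(default_far_dimension(T))
    N = basis.dimension
    if (T - p) * n_u < p * N * N:
        raise ValueError("not enough rows to identify the kernel coefficients")

    Bu = basis.design(grid_u)                      # (n_u, N)
    wq = quad_weights(grid_u)
    c = resid @ (Bu * wq[:, None])                 # (T, N)

    blocks = []
    for l in range(1, p + 1):
        lagged = c[p - l:T - l]                    # rows t = p..T-1 shifted by l
        blocks.append(np.einsum("ir,tj->tirj", Bu, lagged).reshape((T - p) * n_u, N * N))
    A = np.hstack(blocks)
    y = resid[p:].ravel()
    mu, cond = lstsq_ridge(A, y, cond_threshold, ridge)

    rho = (A @ mu).reshape(T - p, n_u)
    fit = FARFit(p=p, basis=basis, grid_u=grid_u, mu=mu, rho=rho,
                 innovations=resid[p:] - rho, condition=cond)
    return fit


@dataclass
class OrderTestResult:
    """Outcome of one nested FAR(p) vs FAR(p+1) chi-squared test."""

    p_null: int
    statistic: float
    df: int
    p_value: float
    q_eta: int
    q_pi: int
    q_star: int

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _fpca(data: np.ndarray, weights: np.ndarray, var_frac: float, max_dim: int,
          q_fixed: int | None):
    """Weighted FPCA of centered curves; returns (scores, eigvals, eigfuns, q)."""
    sw = np.sqrt(weights)
    U, s, Vt = np.linalg.svd(data * sw[None, :], full_matrices=False)
    eigvals = s**2 / data.shape[0]
    pos = eigvals > max(1e-14, 1e-12 * eigvals[0] if eigvals.size else 0)
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("degenerate curves: covariance operator is null")
    if q_fixed is not None:
        q = min(int(q_fixed), n_pos)
    else:
        frac = np.cumsum(eigvals[:n_pos]) / eigvals[:n_pos].sum()
        q = min(int(np.searchsorted(frac, var_frac) + 1), max_dim, n_pos)
    eigfuns = Vt[:q] / sw[None, :]              # rows are eigenfunctions on the grid
    scores = (data * weights[None, :]) @ eigfuns.T
    return scores, eigvals[:q], eigfuns, q


def far_order_test(resid: np.ndarray, grid_u: np.ndarray, p_null: int,
                   q_eta: int | None = None, q_pi: int | None = None,
                   var_frac: float = 0.9, max_dim: int = 5,
                   z_threshold: float = 0.9, center: bool = True,
                   segments: str = "p_plus_1") -> OrderTestResult:
    """Chi-squared test of H0: FAR(p_null) against FAR(p_null + 1).

    The lagged residual curves are stacked into predictor curves eta_j on
    [0, 1] with P = p_null + 1 segments (segment l carries lag l, rescaled),
    the responses are pi_j = eps_j, and the full functional regression of pi
    on eta is estimated by FPCA projection.  The restriction of the predictor
    eigenfunctions to the last segment yields a Gram matrix A_hat whose
    leading eigen-directions are concentrated on the newest lag; the test
    statistic is the standardized squared norm of the regression coefficients
    along those directions, referred to a chi-squared law with q_pi * q_star
    degrees of freedom.
    """
    resid = np.atleast_2d(np.asarray(resid, dtype=float))
    grid_u = np.asarray(grid_u, dtype=float)
    if not np.all(np.isfinite(resid)):
        raise ValueError("residual curves must be finite")
    T, G = resid.shape
    if segments == "p_plus_1":
        P = p_null + 1
    elif segments == "p":
        P = max(p_null, 1)
    else:
        raise ValueError("segments must be 'p_plus_1' or 'p'")
    if T - P < 10:
        raise ValueError("series too short for the order test")
    Teff = T - P

    # eta_j = [eps_{j-1} | eps_{j-2} | ... | eps_{j-P}] on P segments, pi_j = eps_j
    H = np.hstack([resid[P - l:T - l] for l in range(1, P + 1)])
    Pi = resid[P:]
    if center:
        H = H - H.mean(axis=0)
        Pi = Pi - Pi.mean(axis=0)

    w_seg = np.tile(quad_weights(grid_u) / P, P)
    w_pi = quad_weights(grid_u)

    eta_scores, lam, eta_funs, q_eta_used = _fpca(H, w_seg, var_frac, max_dim, q_eta)
    pi_scores, _, _, q_pi_used = _fpca(Pi, w_pi, var_frac, max_dim, q_pi)
    pi_scores = pi_scores[:, :q_pi_used]

    # FPCA regression estimator of the full operator's projections
    psi = (eta_scores.T @ pi_scores) / Teff / lam[:, None]     # (q_eta, q_pi)

    # restriction of predictor eigenfunctions to the last segment, rescaled to [0, 1]
    last = eta_funs[:, (P - 1) * G:]
    A_hat = (last * w_pi[None, :]) @ last.T                    # (q_eta, q_eta)
    xi, beta = np.linalg.eigh(A_hat)
    order = np.argsort(xi)[::-1]
    xi, beta = xi[order], beta[:, order]
    q_star = int(np.sum(xi >= z_threshold * P))
    if q_star == 0:
        q_star = 1
    Bmat = beta[:, :q_star]                                     # (q_eta, q_star)

    innov = pi_scores - eta_scores @ psi
    C_hat = innov.T @ innov / Teff                              # (q_pi, q_pi)

    Gmat = Bmat.T @ psi                                         # (q_star, q_pi)
    M = Bmat.T @ (Bmat / lam[:, None])                          # B' Lambda^{-1} B
    # statistic = Teff * vec(G)' [C (x) M]^{-1} vec(G) = Teff * tr(G' M^{-1} G C^{-1})
    jitter = 0.0
    for _ in range(3):
        try:
            Minv_G = np.linalg.solve(M + jitter * np.eye(q_star), Gmat)
            Cinv_Gt = np.linalg.solve(C_hat + jitter * np.eye(q_pi_used), Gmat.T)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * max(np.trace(M), np.trace(C_hat)))
            warnings.warn("singular inner matrix in order test; regularizing",
                          RuntimeWarning, stacklevel=2)
    stat = float(Teff * np.sum(Minv_G * Cinv_Gt.T))
    stat = max(stat, 0.0)
    df = q_pi_used * q_star
    p_value = float(stats.chi2.sf(stat, df))
    return OrderTestResult(p_null=p_null, statistic=stat, df=df, p_value=p_value,
                           q_eta=q_eta_used, q_pi=q_pi_used, q_star=q_star)


def select_order(resid: np.ndarray, grid_u: np.ndarray, alpha: float = 0.05,
                 p_max: int = 4, **test_kwargs):
    """Sequential order selection: test p = 0, 1, ... and stop at the first
    non-rejection.  Returns (p_hat, list of OrderTestResult)."""
    if p_max < 0:
        raise ValueError("p_max must be >= 0")
    trail: list[OrderTestResult] = []
    for p in range(p_max + 1):
        res = far_order_test(resid, grid_u, p, **test_kwargs)
        trail.append(res)
        if not res.reject(alpha):
            return p, trail
    warnings.warn(f"all nulls up to p_max={p_max} rejected; returning p_max",
                  RuntimeWarning, stacklevel=2)
    return p_max, trail
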