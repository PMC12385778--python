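"""Log-quantile-density (LQD) transform and its inverse.

Densities live in a constrained, non-linear space (nonnegative, unit
integral).  The LQD transform maps a density d on [0, 1] to the unconstrained
function

    Psi(d)(u) = log q(u) = log (d/du) F^{-1}(u) = -log d(Q(u)),

where Q = F^{-1} is the quantile function and q = Q' the quantile density.
The inverse normalizes by theta = int_0^1 exp f(v) dv, so that
Psi^{-1}(Psi(d)) = d for densities supported on [0, 1]:

    Q(u) = theta^{-1} int_0^u exp f(v) dv,   d(y) = theta / exp f(Q^{-1}(y)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .density import DensityCurve

__all__ = [
    "LQDCurve",
    "QuantileCurve",
    "quantile_from_density",
    "lqd_forward",
    "lqd_inverse",
    "LQDTransformer",
    "default_level_grid",
]

_FLOOR = 1e-12
_TAIL_SLOPE_MIN = 0.1


@dataclass
class QuantileCurve:
    """A quantile function Q(u) on levels in [0, 1], nondecreasing with Q(0)=0, Q(1)=1."""

    grid_u: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid_u = np.asarray(self.grid_u, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < -1e-10):
            raise ValueError("quantile function must be nondecreasing")


@dataclass
class LQDCurve:
    """An LQD-transformed curve f(u) = Psi(d)(u) on interior levels of (0, 1)."""

    grid_u: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid_u = np.asarray(self.grid_u, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid_u[0] <= 0.0 or self.grid_u[-1] >= 1.0:
            raise ValueError("LQD level grid must avoid 0 and 1 exactly")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LQD values must be finite")


def default_level_grid(n_u: int) -> np.ndarray:
    """Midpoint level grid u_i = (i - 0.5) / n_u, excluding the endpoints."""
    return (np.arange(1, n_u + 1) - 0.5) / n_u


def _monotone_inverse(x: np.ndarray, y: np.ndarray):
    """PCHIP interpolant of y as a function of x after deduplicating flats."""
    keep = np.concatenate(([True], np.diff(x) > 1e-14))
    if keep.sum() < 2:
        raise ValueError("function is non-invertible (flat over the domain)")
    return PchipInterpolator(x[keep], y[keep])


def quantile_from_density(d: DensityCurve, grid_u) -> QuantileCurve:
    """Quantile function from a density by cumulative trapezoid + monotone inversion."""
    grid_u = np.asarray(grid_u, dtype=float)
    y, vals = d.grid_y, np.clip(d.values, 0.0, None)
    F = np.concatenate(([0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * np.diff(y))))
    if F[-1] <= 0:
        raise ValueError("density integrates to zero; cannot invert")
    F = F / F[-1]
    inv = _monotone_inverse(F, y)
    q = inv(np.clip(grid_u, 0.0, 1.0))
    q[grid_u <= 0.0] = y[0]
    q[grid_u >= 1.0] = y[-1]
    return QuantileCurve(grid_u, q)


def lqd_forward(d: DensityCurve, grid_u) -> LQDCurve:
    """Psi(d)(u) = -log d(Q(u)), evaluated via the density at the quantiles.

    Computing -log d(Q(u)) is numerically preferable to differentiating the
    interpolated quantile function.  Requires d bounded away from zero; the
    density is floored at 1e-12, and flooring on more than 1% of the grid is
    an error.
    """
    grid_u = np.asarray(grid_u, dtype=float)
    Q = quantile_from_density(d, grid_u)
    dens_interp = PchipInterpolator(d.grid_y, d.values)
    d_at_q = np.asarray(dens_interp(Q.values), dtype=float)
    bad = d_at_q <= _FLOOR
    if bad.mean() > 0.01:
        u_bad = grid_u[bad][0]
        raise ValueError(f"density vanishes at quantile level u={u_bad:.4f}; LQD undefined")
    d_at_q = np.clip(d_at_q, _FLOOR, None)
    return LQDCurve(grid_u, -np.log(d_at_q))


def _explin(g1: np.ndarray, g2: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """int exp(g) dv over segments assuming g linear in v (exact for power laws)."""
    delta = g2 - g1
    small = np.abs(delta) < 1e-8
    safe = np.where(small, 1.0, delta)
    ratio = np.where(small, 1.0 + delta / 2.0, np.expm1(safe) / safe)
    return dv * np.exp(g1) * ratio


def lqd_inverse(f: LQDCurve | np.ndarray, grid_y=None, grid_u=None) -> DensityCurve:
    """Map an LQD curve back to a density on [0, 1].

    The quantile density exp(f) may carry integrable power-law singularities
    at the endpoints (a density vanishing at a boundary makes f diverge
    there).  Each tail is classified from the two-point slope in the
    log-level variable: slopes below the grid's noise scale are treated as
    smooth (quadratic extension in u), larger ones as genuine power laws.
    The level grid is augmented with extension nodes approaching 0 and 1 so
    the quantile function and its inversion stay accurate in the tails, and
    interior segments are integrated with an exponential-linear rule that is
    exact for power-law quantile densities.  The output is guaranteed
    nonnegative with unit trapezoid integral on ``grid_y``.
    """
    if isinstance(f, LQDCurve):
        u, vals = f.grid_u, f.values.copy()
    else:
        if grid_u is None:
            raise ValueError("grid_u required when f is a bare array")
        u, vals = np.asarray(grid_u, dtype=float), np.asarray(f, dtype=float).copy()
    if grid_y is None:
        grid_y = np.linspace(0.0, 1.0, 201)
    grid_y = np.asarray(grid_y, dtype=float)
    if u.size < 3:
        raise ValueError("need at least 3 level points to invert an LQD curve")
    if not np.all(np.isfinite(vals)):
        raise ValueError("LQD curve must be finite")

    vals = vals - vals.max()  # scale invariance of the normalized inverse

    # tail models from the two points nearest each endpoint
    b_lo = (vals[1] - vals[0]) / (np.log(u[1]) - np.log(u[0]))
    b_hi = (vals[-2] - vals[-1]) / (np.log1p(-u[-2]) - np.log1p(-u[-1]))
    if b_lo <= -1.0 or b_hi <= -1.0:
        raise ValueError("quantile density has a non-integrable boundary singularity")

    if abs(b_lo) >= _TAIL_SLOPE_MIN:          # power law: f = a + b log u
        f_lo = lambda uu: vals[0] + b_lo * (np.log(uu) - np.log(u[0]))
        b_lo_eff = b_lo
    else:                                      # smooth: quadratic in u
        poly = np.polyfit(u[:3], vals[:3], 2)
        f_lo = lambda uu: np.polyval(poly, uu)
        b_lo_eff = 0.0
    if abs(b_hi) >= _TAIL_SLOPE_MIN:          # power law: f = a + b log(1-u)
        f_hi = lambda uu: vals[-1] + b_hi * (np.log1p(-uu) - np.log1p(-u[-1]))
        b_hi_eff = b_hi
    else:
        poly_hi = np.polyfit(u[-3:], vals[-3:], 2)
        f_hi = lambda uu: np.polyval(poly_hi, uu)
        b_hi_eff = 0.0

    # augment the level grid toward the endpoints to shrink the tail gaps
    ext = np.geomspace(1e-3, 0.75, 7)
    u_lo_ext = u[0] * ext
    u_hi_ext = 1.0 - (1.0 - u[-1]) * ext[::-1]
    u_aug = np.concatenate((u_lo_ext, u, u_hi_ext))
    vals_aug = np.concatenate((f_lo(u_lo_ext), vals, f_hi(u_hi_ext)))

    # segment masses: lower half in v = log u, upper half in v = -log(1-u)
    n_seg = u_aug.size - 1
    mid = int(np.searchsorted(u_aug, 0.5))
    lo_end = min(max(mid, 1), n_seg)
    masses = np.empty(n_seg)
    vlo = np.log(u_aug)
    glo = vals_aug + vlo
    masses[:lo_end] = _explin(glo[:lo_end], glo[1:lo_end + 1], np.diff(vlo)[:lo_end])
    vhi = -np.log1p(-u_aug)
    ghi = vals_aug - vhi
    masses[lo_end:] = _explin(ghi[lo_end:-1], ghi[lo_end + 1:], np.diff(vhi)[lo_end:])

    # analytic power-law mass beyond the extreme augmented nodes
    mass_lo = np.exp(vals_aug[0]) * u_aug[0] / (b_lo_eff + 1.0)
    mass_hi = np.exp(vals_aug[-1]) * (1.0 - u_aug[-1]) / (b_hi_eff + 1.0)

    u_ext = np.concatenate(([0.0], u_aug, [1.0]))
    Q = np.cumsum(np.concatenate(([0.0, mass_lo], masses, [mass_hi])))
    theta = Q[-1]
    if not (np.isfinite(theta) and theta > 0):
        raise ValueError("non-finite normalizer in inverse LQD transform")
    Q = Q / theta
    Q[-1] = 1.0

    inv = _monotone_inverse(Q, u_ext)  # u as a function of y = Q(u)
    u_of_y = np.clip(inv(np.clip(grid_y, 0.0, 1.0)), 1e-15, 1.0 - 1e-15)

    # f at the needed levels: tails by their models, interior by monotone
    # interpolation in the half-specific log variable
    f_of_u = np.empty_like(u_of_y)
    n_lo_interp = max(mid, 2)
    lo_fit = PchipInterpolator(vlo[:n_lo_interp], vals_aug[:n_lo_interp])
    hi_fit = PchipInterpolator(vhi[min(mid, u_aug.size - 2):],
                               vals_aug[min(mid, u_aug.size - 2):])
    below = u_of_y < u_aug[0]
    above = u_of_y > u_aug[-1]
    lower = (~below) & (~above) & (u_of_y <= 0.5)
    upper = (~below) & (~above) & (u_of_y > 0.5)
    if abs(b_lo) >= _TAIL_SLOPE_MIN:
        f_of_u[below] = f_lo(u_of_y[below])
    else:
        f_of_u[below] = vals_aug[0]
    if abs(b_hi) >= _TAIL_SLOPE_MIN:
        f_of_u[above] = f_hi(u_of_y[above])
    else:
        f_of_u[above] = vals_aug[-1]
    f_of_u[lower] = lo_fit(np.log(u_of_y[lower]))
    f_of_u[upper] = hi_fit(-np.log1p(-u_of_y[upper]))

    dens = theta * np.exp(-np.clip(f_of_u, np.log(theta) - 700.0, None))
    dens = np.clip(np.where(np.isfinite(dens), dens, 0.0), 0.0, None)
    total = np.trapezoid(dens, grid_y)
    if total <= 0:
        raise ValueError("inverse transform produced a null density")
    return DensityCurve(grid_y, dens / total)


class LQDTransformer:
    """Transform density curves to LQD space and back, scikit-learn style.

    ``transform`` accepts a T x G matrix of density values on ``grid_y`` and
    returns a T x n_u matrix of LQD curves on ``grid_u``.
    """

    def __init__(self, grid_u=None, n_levels: int = 100):
        self.grid_u = grid_u
        self.n_levels = n_levels

    def fit(self, X=None, y=None, grid_y=None):
        self.grid_u_ = (np.asarray(self.grid_u, dtype=float) if self.grid_u is not None
                        else default_level_grid(self.n_levels))
        return self

    def transform(self, X, grid_y) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        grid_y = np.asarray(grid_y, dtype=float)
        rows = [lqd_forward(DensityCurve(grid_y, row), self.grid_u_).values for row in X]
        return np.vstack(rows)

    def inverse_transform(self, F, grid_y=None) -> np.ndarray:
        F = np.atleast_2d(np.asarray(F, dtype=float))
        if grid_y is None:
            grid_y = np.linspace(0.0, 1.0, 201)
        rows = [lqd_inverse(row, grid_y=grid_y, grid_u=self.grid_u_).values for row in F]
        return np.vstack(rows)

    def fit_transform(self, X, grid_y):
        return self.fit().transform(X, grid_y)
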