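"""Shared least-squares solver with a ridge fallback for ill-conditioned designs."""

from __future__ import annotations

import warnings

import numpy as np


def quad_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights for curves on a grid inside [0, 1].

    Trapezoid weights on the grid itself, plus end caps extending to 0 and 1
    by constant continuation.  For the uniform midpoint grid (i-1/2)/n this
    reduces exactly to the midpoint rule with weight 1/n per point; for grids
    including the endpoints it reduces to the plain trapezoid rule.
    """
    grid = np.asarray(grid, dtype=float)
    d = np.diff(grid)
    w = np.zeros_like(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    w[0] += grid[0]
    w[-1] += 1.0 - grid[-1]
    return w


def lstsq_ridge(A: np.ndarray, y: np.ndarray, cond_threshold: float = 1e10,
                ridge: float = 1e-8) -> tuple[np.ndarray, float]:
    """Least squares via SVD; falls back to trace-scaled ridge when the
    condition number exceeds ``cond_threshold``.

    Returns (coefficients, condition number of the design).
    """
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the least-squares system")
    coef, _, rank, s = np.linalg.lstsq(A, y, rcond=None)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    if cond > cond_threshold or rank < A.shape[1]:
        warnings.warn(
            f"design condition number {cond:.2e} exceeds {cond_threshold:.0e}; "
            "applying ridge regularization", RuntimeWarning, stacklevel=2)
        G = A.T @ A
        lam = ridge * np.trace(G) / G.shape[0]
        if not lam > 0:
            return np.zeros(A.shape[1]), cond   # null design: null solution
        coef = np.linalg.solve(G + lam * np.eye(G.shape[0]), A.T @ y)
    return coef, cond
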