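"""Univariate B-spline bases and tensor products for bivariate surfaces.

The varying-coefficient surfaces g_m(u, x_m) are approximated in the span of
a tensor-product basis b_r(u) * b*_j(x_m), with b_r a scaled B-spline basis
in the function argument u and b*_j a normalized basis in the index covariate
x_m.  Least-squares fits are invariant to the per-basis scalings, which only
affect coefficient reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BSplineBasis", "TensorSplineBasis", "default_knot_numbers"]


def default_knot_numbers(n: int, T: int, k: int, order: int = 4, rate_constant: float = 1.0):
    """Default basis dimensions N0 = N_m = max(order, round(c * (nT)**(1/6))).

    The (nT)**(1/6) growth keeps the approximation and stochastic errors of
    the tensor-spline fit balanced; the dimension is floored at the spline
    order so the basis is well defined.
    """
    if n < 2 or T < 2:
        raise ValueError("need n >= 2 and T >= 2")
    N = max(order, int(round(rate_constant * (n * T) ** (1.0 / 6.0))))
    return N, [N] * k


@dataclass
class BSplineBasis:
    """Clamped B-spline basis of a given order on [0, 1].

    dimension = n_interior + order; the unscaled functions form a partition
    of unity.  ``scaling`` holds optional per-basis positive multipliers.
    """

    order: int = 4
    n_interior: int = 1
    knot_rule: str = "uniform"
    interior_knots: np.ndarray | None = None
    scaling: np.ndarray | None = None
    knots: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.n_interior < 0:
            raise ValueError("n_interior must be >= 0")
        if self.interior_knots is None:
            if self.knot_rule != "uniform":
                raise ValueError("pass interior_knots explicitly for non-uniform rules")
            self.interior_knots = np.linspace(0.0, 1.0, self.n_interior + 2)[1:-1]
        else:
            self.interior_knots = np.sort(np.asarray(self.interior_knots, dtype=float))
            self.n_interior = self.interior_knots.size
        self.knots = np.concatenate((np.zeros(self.order), self.interior_knots,
                                     np.ones(self.order)))
        if self.scaling is not None:
            self.scaling = np.asarray(self.scaling, dtype=float)
            if self.scaling.shape != (self.dimension,):
                raise ValueError("scaling must have one entry per basis function")

    @classmethod
    def from_dimension(cls, dimension: int, order: int = 4, knot_rule: str = "uniform",
                       data: np.ndarray | None = None) -> "BSplineBasis":
        """Basis with a requested dimension (= interior knots + order)."""
        n_interior = dimension - order
        if n_interior < 0:
            raise ValueError(f"dimension {dimension} below spline order {order}")
        if knot_rule == "quantile":
            if data is None:
                raise ValueError("quantile knots need data")
            probs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
            interior = np.quantile(np.asarray(data, dtype=float), probs)
            return cls(order=order, interior_knots=np.clip(interior, 1e-6, 1 - 1e-6))
        return cls(order=order, n_interior=n_interior)

    @property
    def dimension(self) -> int:
        return self.n_interior + self.order

    def design(self, x, apply_scaling: bool = True) -> np.ndarray:
        """Dense design matrix of basis evaluations at points in [0, 1]."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("evaluation points must lie in [0, 1]")
        mat = BSpline.design_matrix(np.clip(x, 0.0, 1.0), self.knots,
                                    self.order - 1).toarray()
        if apply_scaling and self.scaling is not None:
            mat = mat * self.scaling[None, :]
        return mat

    def with_scaling(self, scaling: np.ndarray) -> "BSplineBasis":
        return BSplineBasis(order=self.order, interior_knots=self.interior_knots,
                            scaling=np.asarray(scaling, dtype=float))


@dataclass
class TensorSplineBasis:
    """Tensor-product spline bases for the k additive surfaces g_m(u, x_m).

    ``basis_u`` carries the sqrt(N0) scaling of the u-margin; each ``basis_x``
    is normalized to unit empirical L2 norm over the observed covariate
    values once ``normalize_x`` is called (pure reporting convention: fitted
    surfaces are unchanged).
    """

    basis_u: BSplineBasis
    basis_x: list[BSplineBasis]

    def __post_init__(self) -> None:
        if not self.basis_x:
            raise ValueError("need at least one covariate basis")

    @classmethod
    def default(cls, n: int, T: int, k: int, order: int = 4, rate_constant: float = 1.0,
                N0: int | None = None, Nm: int | None = None,
                knot_rule: str = "uniform", X: np.ndarray | None = None) -> "TensorSplineBasis":
        N0_auto, Nm_auto = default_knot_numbers(n, T, k, order, rate_constant)
        N0 = N0 if N0 is not None else N0_auto
        Nms = [Nm] * k if Nm is not None else Nm_auto
        bu = BSplineBasis.from_dimension(N0, order)
        bu = bu.with_scaling(np.full(N0, np.sqrt(N0)))
        bx = [BSplineBasis.from_dimension(
                  Nms[m], order, knot_rule,
                  data=None if X is None else X[:, m])
              for m in range(k)]
        return cls(bu, bx)

    @property
    def k(self) -> int:
        return len(self.basis_x)

    @property
    def dims(self) -> list[int]:
        return [b.dimension for b in self.basis_x]

    @property
    def n_coef(self) -> int:
        return self.basis_u.dimension * sum(self.dims)

    def normalize_x(self, X: np.ndarray) -> None:
        """Scale each x-margin basis to unit empirical L2 norm over X[:, m]."""
        for m, b in enumerate(self.basis_x):
            mat = b.design(X[:, m], apply_scaling=False)
            norms = np.sqrt(np.mean(mat**2, axis=0))
            norms = np.where(norms > 1e-12, norms, 1.0)
            self.basis_x[m] = b.with_scaling(1.0 / norms)

    def component_design(self, m: int, grid_u: np.ndarray, x_m: np.ndarray,
                         z_m: np.ndarray) -> np.ndarray:
        """Stacked design block for component m.

        Rows run over (t, i) with i fastest; columns over (r, j) with j
        fastest, matching the coefficient layout lambda[r, j, m].
        Entry = z[t] * b_r(u_i) * b*_j(x[t]).
        """
        if not 0 <= m < self.k:
            raise IndexError(f"component index {m} outside 0..{self.k - 1}")
        Bu = self.basis_u.design(grid_u)                      # (n_u, N0)
        Bx = self.basis_x[m].design(np.atleast_1d(x_m))       # (T, Nm)
        z = np.atleast_1d(np.asarray(z_m, dtype=float))
        block = np.einsum("ir,tj->tirj", Bu, Bx * z[:, None])
        T, n_u = Bx.shape[0], Bu.shape[0]
        return block.reshape(T * n_u, Bu.shape[1] * Bx.shape[1])

    def full_design(self, grid_u: np.ndarray, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Horizontal concatenation of all component design blocks."""
        return np.hstack([self.component_design(m, grid_u, X[:, m], Z[:, m])
                          for m in range(self.k)])

    def coef_slices(self) -> list[slice]:
        out, start = [], 0
        N0 = self.basis_u.dimension
        for Nm in self.dims:
            out.append(slice(start, start + N0 * Nm))
            start += N0 * Nm
        return out

    def surface(self, m: int, coef_m: np.ndarray, u, x) -> np.ndarray:
        """Evaluate sum_{r,j} lambda[r,j] b_r(u) b*_j(x) at paired points."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        x = np.atleast_1d(np.asarray(x, dtype=float))
        Bu = self.basis_u.design(u)
        Bx = self.basis_x[m].design(x)
        N0, Nm = Bu.shape[1], Bx.shape[1]
        lam = np.asarray(coef_m, dtype=float).reshape(N0, Nm)
        return np.einsum("pr,rj,pj->p", Bu, lam, Bx)
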