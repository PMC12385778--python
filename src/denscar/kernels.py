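"""Smoothing kernels on [-1, 1] used by the boundary-corrected density estimator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)


def _uniform(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(np.abs(u) <= 1.0, 0.5, 0.0)


def _triweight(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(np.abs(u) <= 1.0, (35.0 / 32.0) * (1.0 - u**2) ** 3, 0.0)


_KERNELS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "epanechnikov": _epanechnikov,
    "uniform": _uniform,
    "triweight": _triweight,
}


@dataclass
class Kernel:
    """A symmetric, bounded kernel supported on [-1, 1].

    Partial integrals are computed by adaptive quadrature (abs tol 1e-8) and
    cached, since the boundary weight repeatedly needs the same truncated
    integrals.
    """

    name: str = "epanechnikov"
    func: Callable[[np.ndarray], np.ndarray] | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.func is None:
            try:
                self.func = _KERNELS[self.name]
            except KeyError:  # pragma: no cover - guarded by CLI choices
                raise ValueError(f"unknown kernel {self.name!r}") from None

    def __call__(self, u) -> np.ndarray:
        return self.func(np.asarray(u, dtype=float))

    def integral(self, a: float, b: float) -> float:
        """Integral of the kernel over [a, b] (clipped to the support)."""
        a = max(float(a), -1.0)
        b = min(float(b), 1.0)
        if b <= a:
            return 0.0
        key = (round(a, 12), round(b, 12))
        if key not in self._cache:
            val, _ = quad(self.func, a, b, epsabs=1e-8, limit=200)
            self._cache[key] = val
        return self._cache[key]


_INSTANCES: dict[str, Kernel] = {}


def get_kernel(kernel: str | Kernel) -> Kernel:
    """Shared kernel instance per name so quadrature caches persist."""
    if isinstance(kernel, Kernel):
        return kernel
    if kernel not in _INSTANCES:
        _INSTANCES[kernel] = Kernel(name=kernel)
    return _INSTANCES[kernel]
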