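"""CSV readers/writers for the file formats the pipeline consumes and emits.

Time indices are 1-based in all files.  Samples come as long format
(t, i, y); covariates as wide format (t, z_1..z_k, x_1..x_k); curve series
(densities, LQD curves, residuals) as long format with one value column.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .density import DensitySampleSeries

__all__ = [
    "read_samples",
    "read_covariates",
    "read_curves",
    "write_curves",
    "write_json",
]


def read_samples(path) -> DensitySampleSeries:
    """Long-format sample table with columns t, i, y (t, i 1-based)."""
    df = pd.read_csv(path)
    missing = {"t", "i", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"samples file missing columns {sorted(missing)}")
    wide = df.pivot(index="t", columns="i", values="y").sort_index()
    if wide.isna().any().any():
        raise ValueError("unbalanced sample table: every t needs the same replicates")
    values = wide.to_numpy(dtype=float)
    if values.min() < 0 or values.max() > 1:
        return DensitySampleSeries.from_raw(values)
    return DensitySampleSeries(values)


def read_covariates(path) -> tuple[np.ndarray, np.ndarray]:
    """Covariate table t, z_1..z_k, x_1..x_k; returns (Z, X) as T x k arrays."""
    df = pd.read_csv(path).sort_values("t")
    z_cols = sorted((c for c in df.columns if c.startswith("z_")),
                    key=lambda c: int(c.split("_")[1]))
    x_cols = sorted((c for c in df.columns if c.startswith("x_")),
                    key=lambda c: int(c.split("_")[1]))
    if not z_cols or len(z_cols) != len(x_cols):
        raise ValueError("covariate file needs matching z_m and x_m columns")
    return df[z_cols].to_numpy(dtype=float), df[x_cols].to_numpy(dtype=float)


def read_curves(path, value_col: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Curve series (t, u|y, value); returns (grid, T x G matrix)."""
    df = pd.read_csv(path)
    axis_col = "u" if "u" in df.columns else "y"
    if value_col is None:
        value_col = next(c for c in df.columns if c not in ("t", axis_col))
    wide = df.pivot(index="t", columns=axis_col, values=value_col).sort_index()
    grid = wide.columns.to_numpy(dtype=float)
    return grid, wide.to_numpy(dtype=float)


def write_curves(path, grid: np.ndarray, values: np.ndarray,
                 axis_name: str = "u", value_name: str = "value") -> None:
    values = np.atleast_2d(values)
    T, G = values.shape
    df = pd.DataFrame({
        "t": np.repeat(np.arange(1, T + 1), G),
        axis_name: np.tile(np.asarray(grid, dtype=float), T),
        value_name: values.ravel(),
    })
    df.to_csv(path, index=False, float_format="%.17g")


def write_json(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
        fh.write("\n")
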