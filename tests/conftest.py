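import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_y():
    return np.linspace(0.0, 1.0, 401)


def smooth_density(grid, kind="poly"):
    """Smooth test densities bounded away from zero on [0, 1]."""
    if kind == "poly":
        v = 0.5 + 3 * grid**2 * (1 - grid)
    elif kind == "sine":
        v = 1 + 0.5 * np.sin(2 * np.pi * grid)
    else:
        raise ValueError(kind)
    return v / np.trapezoid(v, grid)
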