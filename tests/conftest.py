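import numpy as np
import pytest

from lagnet.matrix import ExpressionMatrix, InterpolatedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_interp(values, spacing=1.0, ids=None, scale="log2_ratio"):
    """Build an InterpolatedMatrix from a 2-D array on a uniform grid."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_grid = values.shape
    if ids is None:
        ids = [f"G{i + 1}" for i in range(n_genes)]
    times = np.arange(n_grid) * spacing
    return InterpolatedMatrix(ids, times, values, scale)


def make_expr(values, times, ids=None, scale="raw"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if ids is None:
        ids = [f"G{i + 1}" for i in range(values.shape[0])]
    return ExpressionMatrix(ids, np.asarray(times, dtype=float), values, scale)


@pytest.fixture
def smooth_pair(rng):
    """Two smooth, weakly related regulator curves plus their grid."""
    n = 60
    t = np.arange(n) * 1.0
    x1 = np.sin(2 * np.pi * t / 30.0) + 0.3 * np.sin(2 * np.pi * t / 11.0 + 1.0)
    x2 = np.cos(2 * np.pi * t / 23.0) + 0.2 * np.sin(2 * np.pi * t / 7.0 + 0.5)
    return t, x1, x2
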