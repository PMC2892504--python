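"""Preprocessing of raw time courses.

Three steps turn observed matrices into the uniform, baseline-relative
form the delay regression consumes: log2-ratio transformation against
the first time point, merging of replicate time courses on a shared
lifeline, and cubic-spline interpolation onto a uniform grid.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .matrix import ExpressionMatrix, InterpolatedMatrix

log = logging.getLogger(__name__)

#: Two replicate time labels closer than this (minutes) are the same time.
TIME_TOL = 1e-6


def to_log_ratio(expr: ExpressionMatrix, log_transform: bool = False) -> ExpressionMatrix:
    """Convert to log2 ratios relative to the first time point.

    If ``log_transform`` is true, values are log2-transformed first
    (requires strictly positive input).  Afterwards each row has its
    first-column value subtracted, so the first column is exactly zero:
    all later values are expression changes relative to the baseline.
    """
    if expr.scale == "log2_ratio":
        warnings.warn("matrix is already on log2_ratio scale; returning it unchanged")
        return expr
    if expr.n_times < 2:
        raise ValueError("need at least 2 time points to form ratios against a baseline")
    vals = expr.values.copy()
    if log_transform:
        bad = np.argwhere(vals <= 0)
        if bad.size:
            g = expr.gene_ids[bad[0, 0]]
            raise ValueError(
                f"non-positive value for gene {g!r} at time "
                f"{expr.time_points[bad[0, 1]]}; cannot log-transform"
            )
        vals = np.log2(vals)
    vals = vals - vals[:, :1]
    return ExpressionMatrix(list(expr.gene_ids), expr.time_points.copy(), vals, "log2_ratio")


def drop_incomplete_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with any missing observation, logging the count."""
    keep = ~np.isnan(expr.values).any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d genes with missing observations", n_drop)
    ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(ids, expr.time_points.copy(), expr.values[keep].copy(), expr.scale)


def merge_replicates(
    a: ExpressionMatrix, b: ExpressionMatrix, time_tol: float = TIME_TOL
) -> ExpressionMatrix:
    """Merge two replicate time courses on their common lifeline.

    The output columns are the sorted union of both time-point sets;
    where both replicates measured the same time (within ``time_tol``
    minutes) the values are averaged.  Gene sets must agree.
    """
    if a.scale != b.scale:
        raise ValueError(f"replicates on different scales: {a.scale} vs {b.scale}")
    if set(a.gene_ids) != set(b.gene_ids):
        diff = sorted(set(a.gene_ids) ^ set(b.gene_ids))
        raise ValueError(f"replicates have mismatched gene sets; differing ids: {diff}")
    if b.n_times == 0:
        return a
    if a.n_times == 0:
        return b.subset(a.gene_ids) if a.gene_ids else b

    b = b.subset(a.gene_ids)  # align row order to a
    # tag each column with its source, sort by time, merge near-equal times
    tagged = sorted(
        [(t, 0, j) for j, t in enumerate(a.time_points)]
        + [(t, 1, j) for j, t in enumerate(b.time_points)]
    )
    merged_times: list[float] = []
    merged_cols: list[np.ndarray] = []
    group: list[tuple[float, int, int]] = []

    def flush() -> None:
        if not group:
            return
        cols = [a.values[:, j] if src == 0 else b.values[:, j] for _, src, j in group]
        merged_times.append(float(np.mean([t for t, _, _ in group])))
        merged_cols.append(np.mean(cols, axis=0))

    for item in tagged:
        if group and item[0] - group[-1][0] > time_tol:
            flush()
            group = []
        group.append(item)
    flush()

    values = np.column_stack(merged_cols)
    return ExpressionMatrix(list(a.gene_ids), np.asarray(merged_times), values, a.scale)


def bspline_interpolate(
    expr: ExpressionMatrix,
    n_out: int = 100,
    bc_type: str = "natural",
    allow_linear: bool = False,
) -> InterpolatedMatrix:
    """Interpolate each gene onto ``n_out`` uniformly spaced time points.

    A cubic interpolating spline (no smoothing) is fitted per gene
    through the observed ``(time, value)`` pairs and evaluated on a
    uniform grid spanning the observed range, so observed values are
    reproduced exactly at coinciding grid times.  ``bc_type`` selects
    the spline boundary condition (default natural: zero second
    derivative at the ends).  With fewer than 4 observed points cubic
    interpolation is impossible; pass ``allow_linear=True`` to fall
    back to piecewise-linear interpolation.
    """
    if n_out < expr.n_times:
        raise ValueError(
            f"n_out={n_out} is smaller than the {expr.n_times} observed time points"
        )
    if expr.n_times < 4 and not allow_linear:
        raise ValueError(
            "cubic spline interpolation needs at least 4 time points; "
            "pass allow_linear=True for piecewise-linear interpolation"
        )
    t = expr.time_points
    grid = np.linspace(t[0], t[-1], n_out)
    if expr.n_times < 4:
        f = interp1d(t, expr.values, axis=1)
        out = f(grid)
    else:
        spline = CubicSpline(t, expr.values, axis=1, bc_type=bc_type)
        out = spline(grid)
    spacing = (t[-1] - t[0]) / (n_out - 1)
    return InterpolatedMatrix(
        list(expr.gene_ids), grid, out, expr.scale,
        grid_spacing=spacing, n_grid=n_out,
    )
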