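"""Time-lagged linear regression of a target gene on delayed regulators.

The model for a target g observed on a uniform time grid is

    g(t) = b0 + sum_i a_i * tf_i(t - dt_i) + e(t)

where each regulator tf_i acts with its own delay dt_i, an integer
number of grid steps.  A positive coefficient a_i reads as activation,
a negative one as repression.  Model comparison uses the Gaussian
profile-likelihood AIC and model acceptance uses the adjusted R^2.

All fits for one target share a fixed window starting at
``window_start`` grid steps, so the sample size n is identical across
delays and regulator sets and their AIC values are comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import InterpolatedMatrix

log = logging.getLogger(__name__)

#: Residual-sum-of-squares floor (per sample) for saturated fits, so the
#: AIC stays finite and a perfect model still wins every comparison.
RSS_EPS = 1e-12


@dataclass(frozen=True)
class DelayAssignment:
    """One regulator with its delay in grid steps and in minutes."""

    regulator_id: str
    delay_steps: int
    delay_minutes: float

    def __post_init__(self) -> None:
        if self.delay_steps < 0:
            raise ValueError("delay_steps must be >= 0")

    @classmethod
    def from_steps(
        cls, regulator_id: str, delay_steps: int, grid_spacing: float
    ) -> "DelayAssignment":
        return cls(regulator_id, int(delay_steps), delay_steps * grid_spacing)


@dataclass
class LinearFit:
    """An ordinary-least-squares fit of the delayed linear model.

    ``k_params`` counts the regulators plus intercept plus residual
    variance; ``aic = n*ln(rss/n) + 2*k_params``.  ``adj_r2`` is NaN
    when the sample is too small to define it, which fails any cutoff.
    """

    intercept: float
    coefficients: np.ndarray
    rss: float
    n: int
    k_params: int
    aic: float
    r2: float
    adj_r2: float
    saturated: bool = False
    dropped: tuple[int, ...] = field(default_factory=tuple)


def compute_aic(rss: float, n: int, k_params: int) -> float:
    """Gaussian profile-form AIC, ``n*ln(rss/n) + 2*k_params``.

    Additive constants of the log-likelihood are dropped; all model
    comparisons for one target share the same n, so any affine-
    equivalent AIC variant ranks models identically.  A saturated fit
    (``rss`` below ``n * 1e-12``, including the exact-fit rounding
    residue of order 1e-30) is floored at ``n * 1e-12`` so the AIC
    stays finite and stable while the perfect model still wins every
    comparison through its smaller parameter penalty.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if k_params < 1:
        raise ValueError("k_params must be >= 1")
    if rss <= n * RSS_EPS:
        rss = n * RSS_EPS
    return n * math.log(rss / n) + 2 * k_params


def compute_adj_r2(r2: float, k_s: int, n_r: int) -> float:
    """Adjusted R^2: ``1 - (1 - r2) * (k_s - 1) / (k_s - n_r - 1)``.

    ``k_s`` is the sample size and ``n_r`` the number of regulators.
    Undefined when ``k_s <= n_r + 1``; returns NaN then, which compares
    False against any cutoff.
    """
    if n_r < 0:
        raise ValueError("n_r must be >= 0")
    if k_s <= n_r + 1:
        return float("nan")
    return 1.0 - (1.0 - r2) * (k_s - 1) / (k_s - n_r - 1)


def shift_align(
    mat: InterpolatedMatrix,
    target_id: str,
    assignments: list[DelayAssignment],
    window_start: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the delay-aligned regression design.

    The target vector holds the target's values at grid indices
    ``window_start .. n_grid-1``; the regressor column for a delay-d
    assignment holds the regulator's values at indices shifted back by
    d.  All columns share length ``n_grid - window_start``.
    """
    delays = [a.delay_steps for a in assignments]
    if delays and max(delays) > window_start:
        raise ValueError(
            f"delay {max(delays)} exceeds window_start {window_start}; "
            "the aligned window would run off the front of the grid"
        )
    if window_start < 0 or window_start >= mat.n_grid:
        raise ValueError(f"window_start {window_start} outside grid of {mat.n_grid}")
    y = mat.row(target_id)[window_start:]
    cols = [
        mat.row(a.regulator_id)[window_start - a.delay_steps : mat.n_grid - a.delay_steps]
        for a in assignments
    ]
    X = np.column_stack(cols) if cols else np.empty((y.size, 0))
    return y, X


def _independent_columns(design: np.ndarray) -> list[int]:
    """Greedily keep columns (in order) that increase the design rank."""
    keep: list[int] = []
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    return keep


def fit_delay_model(
    mat: InterpolatedMatrix,
    target_id: str,
    assignments: list[DelayAssignment],
    window_start: int,
) -> LinearFit:
    """OLS fit of the aligned target on the aligned regressors plus intercept.

    Rank-deficient designs (a regulator duplicated at the same delay, a
    constant column) have the offending columns dropped with a logged
    warning; their coefficients are reported as zero.
    """
    y, X = shift_align(mat, target_id, assignments, window_start)
    n = y.size
    design = np.column_stack([np.ones(n), X])
    dropped: tuple[int, ...] = ()
    if X.shape[1] and np.linalg.matrix_rank(design) < design.shape[1]:
        keep = _independent_columns(design)
        dropped = tuple(j - 1 for j in range(design.shape[1]) if j not in keep)
        log.warning(
            "rank-deficient design for target %s: dropping regressor columns %s",
            target_id, dropped,
        )
        design = design[:, keep]
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)

    coefs = np.zeros(len(assignments))
    pos = 1
    for j in range(len(assignments)):
        if j not in dropped:
            coefs[j] = beta[pos]
            pos += 1

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0:
        r2 = min(1.0, max(0.0, 1.0 - rss / tss))
    else:  # constant target: define r2 by whether the fit is exact
        r2 = 1.0 if rss <= n * RSS_EPS else 0.0
    k_params = len(assignments) + 2
    saturated = rss <= n * RSS_EPS
    return LinearFit(
        intercept=float(beta[0]),
        coefficients=coefs,
        rss=rss,
        n=n,
        k_params=k_params,
        aic=compute_aic(rss, n, k_params),
        r2=r2,
        adj_r2=compute_adj_r2(r2, n, len(assignments)),
        saturated=saturated,
        dropped=dropped,
    )


def scan_single_regulator(
    mat: InterpolatedMatrix,
    target_id: str,
    regulator_id: str,
    max_delay_steps: int,
    window_start: int | None = None,
) -> tuple[DelayAssignment, LinearFit]:
    """Best single-regulator model over all delays ``0 .. max_delay_steps``.

    Returns the delay minimizing the AIC with its fit; ties break toward
    the smaller delay.  ``window_start`` defaults to ``max_delay_steps``
    so the sample is identical across the traversed delays.
    """
    if regulator_id == target_id:
        raise ValueError("a gene cannot be scanned as its own regulator")
    if window_start is None:
        window_start = max_delay_steps
    if max_delay_steps > window_start:
        raise ValueError("max_delay_steps must not exceed window_start")
    best: tuple[DelayAssignment, LinearFit] | None = None
    for d in range(max_delay_steps + 1):
        a = DelayAssignment.from_steps(regulator_id, d, mat.grid_spacing)
        fit = fit_delay_model(mat, target_id, [a], window_start)
        if best is None or fit.aic < best[1].aic:
            best = (a, fit)
    assert best is not None
    return best
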