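"""Two-step regulator selection per target gene.

Step 1 screens every candidate regulator with a single-regulator delay
scan: candidates whose best model misses the single-regressor adjusted
R^2 cutoff are dropped, the survivors are ranked by their best AIC.

Step 2 runs AIC forward selection seeded with the top-ranked regulator.
Each remaining candidate is tested in ranking order: its delays are
traversed with the already-selected delays frozen, and the candidate
joins the model only if its best addition strictly lowers the AIC.
After selection, regulators whose coefficient magnitude falls outside
the configured bounds are removed and the model refitted, iteratively.
The final model is accepted only if its adjusted R^2 reaches the
multiple-regression cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .matrix import InterpolatedMatrix
from .regression import (
    DelayAssignment,
    LinearFit,
    fit_delay_model,
    scan_single_regulator,
)

log = logging.getLogger(__name__)


@dataclass
class SelectionParams:
    """Tuning parameters of the selection procedure.

    Defaults reproduce the published setting: screening cutoff 0.8,
    final-model cutoff 0.9, maximum delay one tenth of the interpolated
    grid, and coefficient magnitudes confined to [0.25, 4].
    """

    single_adj_r2_cutoff: float = 0.8
    multiple_adj_r2_cutoff: float = 0.9
    max_delay_steps: int | None = None  # None: floor(max_delay_frac * n_grid)
    max_delay_frac: float = 0.1
    min_coef: float = 0.25
    max_coef: float = 4.0
    restart_prefixes: bool = False
    bound_during_selection: bool = False

    def __post_init__(self) -> None:
        for name in ("single_adj_r2_cutoff", "multiple_adj_r2_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.min_coef < self.max_coef:
            raise ValueError("need 0 <= min_coef < max_coef")
        if self.max_delay_steps is not None and self.max_delay_steps < 0:
            raise ValueError("max_delay_steps must be >= 0")
        if self.max_delay_frac < 0:
            raise ValueError("max_delay_frac must be >= 0")

    def resolve_max_delay(self, n_grid: int) -> int:
        if self.max_delay_steps is not None:
            return self.max_delay_steps
        return math.floor(self.max_delay_frac * n_grid)


class RankingEntry(NamedTuple):
    regulator_id: str
    assignment: DelayAssignment
    aic: float
    adj_r2: float


@dataclass
class RegulatorRanking:
    """Screened candidates for one target, sorted by single-fit AIC."""

    target_id: str
    entries: list[RankingEntry]

    def __len__(self) -> int:
        return len(self.entries)


class RegulatorTerm(NamedTuple):
    regulator_id: str
    delay_steps: int
    delay_minutes: float
    coefficient: float


@dataclass
class TargetModel:
    """The accepted delayed linear model of one target gene."""

    target_id: str
    regulators: list[RegulatorTerm]
    intercept: float
    aic: float
    adj_r2: float
    grid_spacing: float

    def write_tsv(self, path: str | Path) -> None:
        """One tab-separated file per target, header lines then terms."""
        lines = [
            f"# target\t{self.target_id}",
            f"# intercept\t{self.intercept:.10g}",
            f"# aic\t{self.aic:.10g}",
            f"# adj_r2\t{self.adj_r2:.10g}",
            "regulator\tcoefficient\tdelay_steps\tdelay_minutes",
        ]
        for r in self.regulators:
            lines.append(
                f"{r.regulator_id}\t{r.coefficient:.10g}\t"
                f"{r.delay_steps}\t{r.delay_minutes:.10g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def screen_and_rank(
    mat: InterpolatedMatrix,
    target_id: str,
    candidates: Sequence[str],
    params: SelectionParams,
) -> RegulatorRanking:
    """Screen candidates by their best single-regulator fit and rank them.

    A candidate survives if the adjusted R^2 of its best-AIC single
    model (over all delays) reaches the single-regressor cutoff.
    Survivors are sorted by that AIC ascending; the sort is stable, so
    ties keep the candidate input order.  Self-regulation is excluded.
    """
    max_d = params.resolve_max_delay(mat.n_grid)
    entries: list[RankingEntry] = []
    for cand in candidates:
        if cand == target_id:
            continue
        assignment, fit = scan_single_regulator(mat, target_id, cand, max_d)
        if fit.adj_r2 >= params.single_adj_r2_cutoff:  # NaN fails
            entries.append(RankingEntry(cand, assignment, fit.aic, fit.adj_r2))
    entries.sort(key=lambda e: e.aic)
    return RegulatorRanking(target_id, entries)


def _coef_in_bounds(c: float, params: SelectionParams) -> bool:
    return params.min_coef <= abs(c) <= params.max_coef


def _forward_pass(
    mat: InterpolatedMatrix,
    target_id: str,
    seed: list[DelayAssignment],
    rest: Iterable[RankingEntry],
    params: SelectionParams,
    max_d: int,
) -> tuple[list[DelayAssignment], LinearFit]:
    window = max_d
    selected = list(seed)
    current = fit_delay_model(mat, target_id, selected, window)
    for entry in rest:
        best_fit: LinearFit | None = None
        best_assign: DelayAssignment | None = None
        for d in range(max_d + 1):
            trial = DelayAssignment.from_steps(entry.regulator_id, d, mat.grid_spacing)
            fit = fit_delay_model(mat, target_id, selected + [trial], window)
            if fit.dropped:
                log.info(
                    "candidate %s at delay %d makes the design for %s rank-"
                    "deficient; skipped", entry.regulator_id, d, target_id,
                )
                continue
            if best_fit is None or fit.aic < best_fit.aic:
                best_fit, best_assign = fit, trial
        if best_fit is None or best_assign is None:
            continue
        if params.bound_during_selection and not _coef_in_bounds(
            best_fit.coefficients[-1], params
        ):
            continue
        if best_fit.aic < current.aic:
            selected.append(best_assign)
            current = best_fit
        else:
            log.debug(
                "candidate %s rejected for %s (AIC %.4f >= %.4f)",
                entry.regulator_id, target_id, best_fit.aic, current.aic,
            )
    return selected, current


def forward_select(
    mat: InterpolatedMatrix,
    target_id: str,
    ranking: RegulatorRanking,
    params: SelectionParams,
) -> tuple[list[DelayAssignment], LinearFit]:
    """AIC forward selection of regulators and their delays.

    The selected set starts from the top-ranked regulator at its best
    single-fit delay.  Remaining candidates are tested in ranking order;
    for each, all delays are traversed with the selected delays held
    fixed, and the candidate is admitted only if its best addition
    strictly lowers the AIC.  With ``restart_prefixes`` the pass is
    repeated seeded from every ranking prefix (each at its single-fit
    delays) and the lowest-AIC outcome wins.
    """
    if not ranking.entries:
        raise ValueError(f"empty ranking for target {target_id}")
    max_d = params.resolve_max_delay(mat.n_grid)
    if not params.restart_prefixes:
        return _forward_pass(
            mat, target_id, [ranking.entries[0].assignment],
            ranking.entries[1:], params, max_d,
        )
    best: tuple[list[DelayAssignment], LinearFit] | None = None
    for i in range(len(ranking.entries)):
        seed = [e.assignment for e in ranking.entries[: i + 1]]
        selected, fit = _forward_pass(
            mat, target_id, seed, ranking.entries[i + 1 :], params, max_d
        )
        if best is None or fit.aic < best[1].aic:
            best = (selected, fit)
    assert best is not None
    return best


def enforce_coef_bounds(
    mat: InterpolatedMatrix,
    target_id: str,
    assignments: list[DelayAssignment],
    fit: LinearFit,
    params: SelectionParams,
    window_start: int,
) -> tuple[list[DelayAssignment], LinearFit | None]:
    """Iteratively drop regulators with out-of-bounds coefficients and refit.

    Repeats until every remaining coefficient magnitude lies within
    ``[min_coef, max_coef]`` or no regulator remains (returned as an
    empty assignment list with fit ``None``).
    """
    assignments = list(assignments)
    while assignments:
        keep = [
            a for a, c in zip(assignments, fit.coefficients)
            if _coef_in_bounds(float(c), params)
        ]
        if len(keep) == len(assignments):
            return assignments, fit
        if not keep:
            return [], None
        assignments = keep
        fit = fit_delay_model(mat, target_id, assignments, window_start)
    return [], None


def fit_target_model(
    mat: InterpolatedMatrix,
    target_id: str,
    candidates: Sequence[str],
    params: SelectionParams | None = None,
) -> TargetModel | None:
    """Full selection pipeline for one target; None when no model passes."""
    model, _ = fit_target_model_detail(mat, target_id, candidates, params)
    return model


def fit_target_model_detail(
    mat: InterpolatedMatrix,
    target_id: str,
    candidates: Sequence[str],
    params: SelectionParams | None = None,
) -> tuple[TargetModel | None, str]:
    """As :func:`fit_target_model`, also reporting which gate failed.

    The second element is ``"ok"``, ``"screened_out"`` (no candidate
    passed the single-regressor cutoff), ``"coef_bounds_emptied"`` or
    ``"below_multiple_cutoff"``.
    """
    if params is None:
        params = SelectionParams()
    if target_id not in mat:
        raise KeyError(f"target id not in matrix: {target_id!r}")
    max_d = params.resolve_max_delay(mat.n_grid)
    ranking = screen_and_rank(mat, target_id, candidates, params)
    if not ranking.entries:
        return None, "screened_out"
    assignments, fit = forward_select(mat, target_id, ranking, params)
    assignments, bounded = enforce_coef_bounds(
        mat, target_id, assignments, fit, params, max_d
    )
    if not assignments or bounded is None:
        return None, "coef_bounds_emptied"
    if not bounded.adj_r2 >= params.multiple_adj_r2_cutoff:  # NaN-safe
        return None, "below_multiple_cutoff"
    terms = [
        RegulatorTerm(a.regulator_id, a.delay_steps, a.delay_minutes, float(c))
        for a, c in zip(assignments, bounded.coefficients)
    ]
    model = TargetModel(
        target_id=target_id,
        regulators=terms,
        intercept=bounded.intercept,
        aic=bounded.aic,
        adj_r2=bounded.adj_r2,
        grid_spacing=mat.grid_spacing,
    )
    return model, "ok"


def fit_all_targets(
    mat: InterpolatedMatrix,
    targets: Sequence[str],
    candidates: Sequence[str],
    params: SelectionParams | None = None,
    skip_log: dict[str, str] | None = None,
) -> list[TargetModel]:
    """Fit every target independently; targets without an accepted model
    are omitted from the result (and recorded in ``skip_log`` if given).
    """
    unknown = [g for g in list(targets) + list(candidates) if g not in mat]
    if unknown:
        raise KeyError(f"ids not in matrix: {sorted(set(unknown))}")
    models: list[TargetModel] = []
    n_skip = 0
    for tgt in targets:
        model, reason = fit_target_model_detail(mat, tgt, candidates, params)
        if model is not None:
            models.append(model)
        else:
            n_skip += 1
            if skip_log is not None:
                skip_log[tgt] = reason
            log.info("target %s skipped: %s", tgt, reason)
    log.info("modeled %d targets, skipped %d", len(models), n_skip)
    return models
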