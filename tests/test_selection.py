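"""Screening, AIC forward selection and coefficient-bound enforcement."""

import itertools

import numpy as np
import pytest

from lagnet.regression import DelayAssignment, fit_delay_model
from lagnet.selection import (
    SelectionParams,
    enforce_coef_bounds,
    fit_all_targets,
    fit_target_model,
    fit_target_model_detail,
    forward_select,
    screen_and_rank,
)

from conftest import make_interp


def delayed(series, d):
    out = np.empty_like(series)
    out[d:] = series[: series.size - d] if d else series
    out[:d] = series[0]
    return out


@pytest.fixture
def two_regulator_fixture(smooth_pair, rng):
    """Target = 0.2 + 0.8*x1(t-2) - 0.5*x2(t-4), plus a white-noise decoy."""
    _, x1, x2 = smooth_pair
    decoy = rng.normal(size=x1.size)
    target = 0.2 + 0.8 * delayed(x1, 2) - 0.5 * delayed(x2, 4)
    mat = make_interp([x1, x2, decoy, target], ids=["R1", "R2", "DECOY", "T"])
    return mat


class TestScreenAndRank:
    def test_noise_gene_filtered(self, smooth_pair, rng):
        _, x1, _ = smooth_pair
        noise = rng.normal(size=x1.size)
        target = 0.7 * delayed(x1, 1)
        mat = make_interp([x1, noise, target], ids=["R", "NOISE", "T"])
        params = SelectionParams(max_delay_steps=5)
        ranking = screen_and_rank(mat, "T", ["R", "NOISE"], params)
        assert [e.regulator_id for e in ranking.entries] == ["R"]

    def test_empty_candidate_pool(self, smooth_pair):
        _, x1, _ = smooth_pair
        mat = make_interp([x1], ids=["T"])
        params = SelectionParams(max_delay_steps=3)
        assert len(screen_and_rank(mat, "T", ["T"], params)) == 0

    def test_sorted_by_aic_ascending(self, two_regulator_fixture):
        params = SelectionParams(max_delay_steps=6, single_adj_r2_cutoff=0.05)
        ranking = screen_and_rank(
            two_regulator_fixture, "T", ["R1", "R2", "DECOY"], params
        )
        aics = [e.aic for e in ranking.entries]
        assert aics == sorted(aics)
        assert all(e.adj_r2 >= 0.05 for e in ranking.entries)


def exhaustive_best(mat, target_id, candidates, max_d, window):
    """Brute-force minimum AIC over all subsets x delay tuples."""
    best = (np.inf, None)
    for r in range(1, len(candidates) + 1):
        for sub in itertools.combinations(candidates, r):
            for dl in itertools.product(range(max_d + 1), repeat=r):
                assigns = [
                    DelayAssignment.from_steps(g, d, mat.grid_spacing)
                    for g, d in zip(sub, dl)
                ]
                fit = fit_delay_model(mat, target_id, assigns, window)
                if fit.aic < best[0]:
                    best = (fit.aic, assigns)
    return best


class TestForwardSelect:
    def test_recovers_two_regulator_truth_exactly(self, two_regulator_fixture):
        mat = two_regulator_fixture
        params = SelectionParams(max_delay_steps=6, single_adj_r2_cutoff=0.05)
        ranking = screen_and_rank(mat, "T", ["R1", "R2", "DECOY"], params)
        selected, fit = forward_select(mat, "T", ranking, params)
        got = {(a.regulator_id, a.delay_steps) for a in selected}
        assert got == {("R1", 2), ("R2", 4)}
        coefs = dict(zip([a.regulator_id for a in selected], fit.coefficients))
        assert coefs["R1"] == pytest.approx(0.8, abs=1e-6)
        assert coefs["R2"] == pytest.approx(-0.5, abs=1e-6)
        # greedy equals the exhaustive optimum here
        best_aic, _ = exhaustive_best(mat, "T", ["R1", "R2", "DECOY"], 6, 6)
        assert fit.aic == pytest.approx(best_aic)

    def test_singleton_ranking_returns_single_fit(self, smooth_pair):
        _, x1, _ = smooth_pair
        target = 1.1 * delayed(x1, 1)
        mat = make_interp([x1, target], ids=["R", "T"])
        params = SelectionParams(max_delay_steps=4)
        ranking = screen_and_rank(mat, "T", ["R"], params)
        assert len(ranking) == 1
        selected, fit = forward_select(mat, "T", ranking, params)
        assert [a.regulator_id for a in selected] == ["R"]
        assert selected[0] == ranking.entries[0].assignment
        assert fit.aic == pytest.approx(ranking.entries[0].aic)

    def test_accepted_aic_sequence_strictly_decreases(self, two_regulator_fixture):
        mat = two_regulator_fixture
        params = SelectionParams(max_delay_steps=6, single_adj_r2_cutoff=0.05)
        ranking = screen_and_rank(mat, "T", ["R1", "R2", "DECOY"], params)
        selected, _ = forward_select(mat, "T", ranking, params)
        # recompute the AIC of every accepted prefix independently
        aics = [
            fit_delay_model(mat, "T", list(selected[: k + 1]), 6).aic
            for k in range(len(selected))
        ]
        assert all(b < a for a, b in zip(aics, aics[1:]))


class TestEnforceCoefBounds:
    def test_in_bounds_model_unchanged(self, smooth_pair):
        _, x1, _ = smooth_pair
        target = 0.9 * delayed(x1, 1)
        mat = make_interp([x1, target], ids=["R", "T"])
        params = SelectionParams(max_delay_steps=3)
        assigns = [DelayAssignment.from_steps("R", 1, 1.0)]
        fit = fit_delay_model(mat, "T", assigns, 3)
        out_assigns, out_fit = enforce_coef_bounds(mat, "T", assigns, fit, params, 3)
        assert out_assigns == assigns
        assert out_fit is fit

    def test_tiny_coefficient_dropped_and_refit(self, smooth_pair):
        _, x1, x2 = smooth_pair
        target = 0.9 * delayed(x1, 1) + 0.01 * delayed(x2, 2)
        mat = make_interp([x1, x2, target], ids=["R1", "R2", "T"])
        params = SelectionParams(max_delay_steps=3)
        assigns = [
            DelayAssignment.from_steps("R1", 1, 1.0),
            DelayAssignment.from_steps("R2", 2, 1.0),
        ]
        fit = fit_delay_model(mat, "T", assigns, 3)
        out_assigns, out_fit = enforce_coef_bounds(mat, "T", assigns, fit, params, 3)
        assert [a.regulator_id for a in out_assigns] == ["R1"]
        assert out_fit.coefficients[0] == pytest.approx(0.9, abs=0.02)

    def test_all_out_of_bounds_empties_model(self, smooth_pair):
        _, x1, _ = smooth_pair
        target = 0.01 * delayed(x1, 1)
        mat = make_interp([x1, target], ids=["R", "T"])
        params = SelectionParams(max_delay_steps=3)
        assigns = [DelayAssignment.from_steps("R", 1, 1.0)]
        fit = fit_delay_model(mat, "T", assigns, 3)
        out_assigns, out_fit = enforce_coef_bounds(mat, "T", assigns, fit, params, 3)
        assert out_assigns == []
        assert out_fit is None


class TestFitTargetModel:
    def test_independent_target_yields_no_model(self, smooth_pair, rng):
        _, x1, _ = smooth_pair
        indep = rng.normal(size=x1.size)
        mat = make_interp([x1, indep], ids=["R", "T"])
        model, reason = fit_target_model_detail(
            mat, "T", ["R"], SelectionParams(max_delay_steps=5)
        )
        assert model is None
        assert reason == "screened_out"

    def test_gate_reason_below_multiple_cutoff(self, smooth_pair, rng):
        _, x1, _ = smooth_pair
        # strong but imperfect single regulator: passes 0.5 screening,
        # cannot reach an impossible 0.999999 final cutoff
        target = 0.9 * delayed(x1, 1) + rng.normal(0, 0.3, x1.size)
        mat = make_interp([x1, target], ids=["R", "T"])
        params = SelectionParams(
            max_delay_steps=3, single_adj_r2_cutoff=0.5,
            multiple_adj_r2_cutoff=0.999999,
        )
        model, reason = fit_target_model_detail(mat, "T", ["R"], params)
        assert model is None
        assert reason == "below_multiple_cutoff"

    def test_model_respects_invariants(self, two_regulator_fixture):
        params = SelectionParams(max_delay_steps=6, single_adj_r2_cutoff=0.05)
        model = fit_target_model(two_regulator_fixture, "T", ["R1", "R2", "DECOY"], params)
        assert model is not None
        assert model.adj_r2 >= params.multiple_adj_r2_cutoff
        for term in model.regulators:
            assert params.min_coef <= abs(term.coefficient) <= params.max_coef
            assert term.delay_steps <= 6
            assert term.delay_minutes == pytest.approx(
                term.delay_steps * model.grid_spacing
            )

    def test_model_file_round_trip_format(self, two_regulator_fixture, tmp_path):
        params = SelectionParams(max_delay_steps=6, single_adj_r2_cutoff=0.05)
        model = fit_target_model(two_regulator_fixture, "T", ["R1", "R2"], params)
        path = tmp_path / "T.tsv"
        model.write_tsv(path)
        text = path.read_text()
        assert text.startswith("# target\tT\n")
        assert "regulator\tcoefficient\tdelay_steps\tdelay_minutes" in text
        assert len(text.strip().splitlines()) == 5 + len(model.regulators)


class TestFitAllTargets:
    def test_empty_target_list(self, smooth_pair):
        _, x1, _ = smooth_pair
        mat = make_interp([x1], ids=["R"])
        assert fit_all_targets(mat, [], ["R"]) == []

    def test_unknown_ids_rejected_before_fitting(self, smooth_pair):
        _, x1, _ = smooth_pair
        mat = make_interp([x1], ids=["R"])
        with pytest.raises(KeyError, match="NOPE"):
            fit_all_targets(mat, ["NOPE"], ["R"])

    def test_skip_log_records_gates(self, smooth_pair, rng):
        _, x1, _ = smooth_pair
        indep = rng.normal(size=x1.size)
        target = 0.9 * delayed(x1, 1)
        mat = make_interp([x1, indep, target], ids=["R", "INDEP", "T"])
        skip_log = {}
        models = fit_all_targets(
            mat, ["INDEP", "T"], ["R"], SelectionParams(max_delay_steps=3),
            skip_log=skip_log,
        )
        assert [m.target_id for m in models] == ["T"]
        assert skip_log == {"INDEP": "screened_out"}

    def test_deterministic(self, two_regulator_fixture):
        params = SelectionParams(max_delay_steps=6, single_adj_r2_cutoff=0.05)
        runs = [
            fit_all_targets(two_regulator_fixture, ["T"], ["R1", "R2", "DECOY"], params)
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestDelayFreeReduction:
    def test_max_delay_zero_is_plain_forward_regression(self, rng):
        # with max_delay_steps=0 every assignment has delay 0 and the fit
        # window covers the whole series
        X = rng.normal(size=(3, 50))
        y = 0.5 + 1.0 * X[0] - 0.8 * X[1] + rng.normal(0, 0.05, 50)
        mat = make_interp(np.vstack([X, y]), ids=["A", "B", "C", "T"])
        params = SelectionParams(max_delay_steps=0, single_adj_r2_cutoff=0.1)
        model = fit_target_model(mat, "T", ["A", "B", "C"], params)
        assert model is not None
        assert all(t.delay_steps == 0 for t in model.regulators)
        got = {t.regulator_id for t in model.regulators}
        assert got == {"A", "B"}
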