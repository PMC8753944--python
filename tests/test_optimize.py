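"""Objectives, fuzzy normalization, achievement level, and heuristic search."""

import dataclasses

import numpy as np
import pytest

from hospflow.casestudy import SCENARIO_RESULTS
from hospflow.config import default_config
from hospflow.flow import ArrivalSegment, TypeMixWindow
from hospflow.optimize import (
    DEFAULT_WEIGHT_SETS,
    MultiObjective,
    ObjectiveBounds,
    OptimizationResult,
    SearchConfig,
    SearchSpace,
    SingleObjective,
    WeightSet,
    bounds_from_single_objective,
    evaluate,
    feasible,
    lambda_level,
    membership,
    operating_cost,
    search,
)
from hospflow.staffing import CostModel, ResourceSchedule


class TestOperatingCost:
    def test_zero_staffing_zero_cost(self):
        s = ResourceSchedule.uniform({"M1": 0, "M2": 0}, periods=("07-09", "09-11"))
        c = CostModel.unit(s.kinds, s.periods, cost=100.0)
        assert operating_cost(s, c) == 0.0

    def test_arithmetic(self):
        s = ResourceSchedule.from_rows(
            {"M1": [1, 2], "M2": [0, 3]}, ("07-09", "09-11")
        )
        c = CostModel.unit(s.kinds, s.periods, cost=100.0)
        assert operating_cost(s, c) == 600.0

    def test_linearity(self):
        s = ResourceSchedule.from_rows({"M1": [1, 2], "M2": [0, 3]}, ("07-09", "09-11"))
        doubled = ResourceSchedule.from_rows(
            {"M1": [2, 4], "M2": [0, 6]}, ("07-09", "09-11")
        )
        c = CostModel.unit(s.kinds, s.periods, cost=37.5)
        assert operating_cost(doubled, c) == 2 * operating_cost(s, c)

    def test_dimension_mismatch(self):
        s = ResourceSchedule.uniform({"M1": 1}, periods=("07-09",))
        c = CostModel.unit(("M1", "M2"), ("07-09",))
        with pytest.raises(ValueError, match="same kinds"):
            operating_cost(s, c)


class TestFeasibility:
    def test_within_capacity(self):
        s = ResourceSchedule.from_rows(
            {"M1": [4, 5, 5, 4], "M2": [5, 5, 5, 4]},
            ("07-09", "09-11", "11-13", "13-15"),
        )
        assert feasible(s, A=10)

    def test_one_period_over(self):
        s = ResourceSchedule.from_rows(
            {"M1": [4, 6], "M2": [5, 5]}, ("07-09", "09-11")
        )
        assert not feasible(s, A=10)

    def test_nurses_not_counted_against_A(self):
        s = ResourceSchedule.from_rows({"N": [50], "M1": [2]}, ("07-09",))
        assert feasible(s, A=2)

    def test_negative_matrix_rejected(self):
        assert not feasible(np.array([[-1, 0]]), A=10)


class TestMembership:
    BOUNDS_COST = ObjectiveBounds(z_plus=6864.0, z_minus=4521.0, sense="min")
    BOUNDS_SAT = ObjectiveBounds(z_plus=89.95, z_minus=45.9, sense="max")

    def test_min_sense_optimistic_extreme(self):
        assert membership(4521.0, self.BOUNDS_COST) == 1.0

    def test_max_sense_pessimistic_extreme(self):
        assert membership(45.9, self.BOUNDS_SAT) == 0.0

    def test_printed_case_arithmetic(self):
        # (6864 - 4966.5) / (6864 - 4521) = 0.8099
        assert membership(4966.5, self.BOUNDS_COST) == pytest.approx(0.810, abs=1e-3)

    def test_clipping_outside_anchor_interval(self):
        assert membership(4000.0, self.BOUNDS_COST) == 1.0
        assert membership(8000.0, self.BOUNDS_COST) == 0.0

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ObjectiveBounds(z_plus=5.0, z_minus=5.0, sense="min")


class TestLambdaLevel:
    def test_printed_weighted_case(self):
        # memberships of the dedicated-counter weight-(0.8, 0.2) solution
        assert lambda_level((0.810, 0.483), (0.8, 0.2)) == 1.0

    def test_binding_constraint_below_one(self):
        # the known inconsistent one-stop row: f_sat ~= 0.157 < w_sat = 0.2
        lam = lambda_level((0.8432, 0.1567), (0.8, 0.2))
        assert lam == pytest.approx(0.1567 / 0.2, abs=1e-4)

    def test_weights_as_memberships_boundary(self):
        assert lambda_level((0.8, 0.2), (0.8, 0.2)) == 1.0

    def test_zero_weight_constraint_dropped(self):
        assert lambda_level((0.0, 0.9), (0.0, 1.0)) == pytest.approx(0.9)

    def test_membership_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            lambda_level((1.5, 0.5), (0.5, 0.5))


class TestBoundsFromSingleObjective:
    @staticmethod
    def _result(z_cost, z_sat):
        sched = ResourceSchedule.uniform({"M1": 1}, periods=("07-09",))
        return OptimizationResult(sched, z_cost, z_sat, None, 1, [])

    def test_printed_scenario_one(self):
        cost_run = self._result(*SCENARIO_RESULTS[1]["single"]["cost"])
        sat_run = self._result(*SCENARIO_RESULTS[1]["single"]["satisfaction"])
        bounds = bounds_from_single_objective(cost_run, sat_run)
        assert (bounds["cost"].z_minus, bounds["cost"].z_plus) == (4521.0, 6864.0)
        assert (bounds["satisfaction"].z_minus, bounds["satisfaction"].z_plus) == (45.9, 89.95)

    def test_printed_scenario_two_cost_anchors(self):
        cost_run = self._result(*SCENARIO_RESULTS[2]["single"]["cost"])
        sat_run = self._result(*SCENARIO_RESULTS[2]["single"]["satisfaction"])
        bounds = bounds_from_single_objective(cost_run, sat_run)
        assert (bounds["cost"].z_minus, bounds["cost"].z_plus) == (2161.5, 5940.0)

    def test_equal_runs_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            bounds_from_single_objective(self._result(5.0, 50.0), self._result(5.0, 60.0))


# ---------------------------------------------------------------------------
# search vs. brute-force enumeration on a deterministic surrogate


def toy_space():
    return SearchSpace(
        kinds=("M1", "M2"),
        periods=("07-09", "09-11"),
        lower=np.zeros((2, 2), dtype=int),
        upper=np.full((2, 2), 2, dtype=int),
        A=3,
    )


def surrogate(schedule):
    """Deterministic, injective toy objective: diminishing satisfaction
    returns in total staffing, linear cost."""
    n = schedule.n
    z_cost = 100.0 * float(n.sum())
    z_sat = float(
        20.0
        + 10.0 * np.tanh(0.4 * n.sum())
        + 0.021 * n[0, 0]
        + 0.013 * n[0, 1]
        + 0.007 * n[1, 0]
        + 0.003 * n[1, 1]
    )
    return z_cost, z_sat


def brute_force(objective, space, evaluate_fn):
    best = None
    for cand in space.enumerate():
        if not space.is_feasible(cand):
            continue
        z_cost, z_sat = evaluate_fn(space.schedule(cand))
        if isinstance(objective, SingleObjective):
            score = -z_cost if objective.target == "cost" else z_sat
        else:
            score = lambda_level(
                (
                    membership(z_cost, objective.cost_bounds),
                    membership(z_sat, objective.sat_bounds),
                ),
                (objective.weights.w_cost, objective.weights.w_sat),
            )
        if best is None or score > best[0] + 1e-12:
            best = (score, cand.copy(), z_cost, z_sat)
    return best


TOY_BOUNDS = dict(
    cost_bounds=ObjectiveBounds(z_plus=600.0, z_minus=0.0, sense="min"),
    sat_bounds=ObjectiveBounds(z_plus=30.0, z_minus=20.0, sense="max"),
)


class TestSearch:
    @pytest.mark.parametrize(
        "objective",
        [
            SingleObjective("cost"),
            SingleObjective("satisfaction"),
            MultiObjective(WeightSet(0.5, 0.5), **TOY_BOUNDS),
            MultiObjective(WeightSet(0.8, 0.2), **TOY_BOUNDS),
        ],
        ids=["cost", "satisfaction", "w50", "w80"],
    )
    def test_exhaustive_equals_brute_force(self, objective):
        space = toy_space()
        expected = brute_force(objective, space, surrogate)
        res = search(
            objective,
            space,
            surrogate,
            SearchConfig(stop_after_non_improving=space.size(), proposal="exhaustive"),
        )
        assert np.array_equal(res.best_schedule.n, expected[1])
        assert (res.z_cost, res.z_sat) == (expected[2], expected[3])

    def test_cost_only_reaches_lower_corner(self):
        space = toy_space()
        res = search(
            SingleObjective("cost"),
            space,
            surrogate,
            SearchConfig(stop_after_non_improving=200, seed=5),
        )
        assert res.z_cost == 0.0
        assert (res.best_schedule.n == space.lower).all()

    def test_neighborhood_search_finds_toy_optimum(self):
        space = toy_space()
        objective = SingleObjective("satisfaction")
        expected = brute_force(objective, space, surrogate)
        res = search(
            objective, space, surrogate, SearchConfig(stop_after_non_improving=200, seed=1)
        )
        assert np.array_equal(res.best_schedule.n, expected[1])

    def test_reported_lambda_is_consistent(self):
        """Recomputing memberships from the reported (Z_cost, Z_sat)
        reproduces the reported achievement level exactly."""
        objective = MultiObjective(WeightSet(0.4, 0.6), **TOY_BOUNDS)
        res = search(
            objective,
            toy_space(),
            surrogate,
            SearchConfig(stop_after_non_improving=100, proposal="exhaustive"),
        )
        lam = lambda_level(
            (
                membership(res.z_cost, objective.cost_bounds),
                membership(res.z_sat, objective.sat_bounds),
            ),
            (0.4, 0.6),
        )
        assert res.lam == lam

    def test_satisfaction_weakly_monotone_in_weight(self):
        """Across the bundled weight settings, more weight on satisfaction
        never lowers the optimal satisfaction (enumerated oracle)."""
        space = toy_space()
        sats = []
        for w in sorted(DEFAULT_WEIGHT_SETS, key=lambda w: w.w_sat):
            objective = MultiObjective(w, **TOY_BOUNDS)
            _, _, _, z_sat = brute_force(objective, space, surrogate)
            sats.append(z_sat)
        assert all(a <= b + 1e-12 for a, b in zip(sats, sats[1:]))

    def test_empty_feasible_region(self):
        space = SearchSpace(
            kinds=("M1",),
            periods=("07-09",),
            lower=np.array([[5]]),
            upper=np.array([[6]]),
            A=2,
        )
        with pytest.raises(ValueError, match="feasible"):
            search(
                SingleObjective("cost"),
                space,
                surrogate,
                SearchConfig(stop_after_non_improving=10, proposal="exhaustive"),
            )

    def test_trace_logs_every_candidate(self):
        space = toy_space()
        res = search(
            SingleObjective("cost"),
            space,
            surrogate,
            SearchConfig(stop_after_non_improving=30, seed=2),
        )
        assert len(res.trace) >= res.evaluations
        assert all("feasible" in row for row in res.trace)


# ---------------------------------------------------------------------------
# simulation-backed evaluation


@pytest.fixture(scope="module")
def tiny_sim_config():
    """A short, light day: one arrival segment, uniform mix, MR-only types."""
    base = default_config()
    return dataclasses.replace(
        base,
        arrival_segments=[ArrivalSegment(0.0, 600.0, 0.0, 8.0)],
        mix_windows=[TypeMixWindow(0.0, 600.0, (0.25, 0.25, 0.25, 0.25))],
        ticket_close=120.0,
    )


class TestEvaluate:
    def _schedule(self):
        return ResourceSchedule.uniform(
            {"N": 2, "N2": 2, "M1": 1, "M2": 1, "M3": 1, "M4": 1}
        )

    def test_same_seed_identical(self, tiny_sim_config):
        s = self._schedule()
        c = CostModel.unit(s.kinds, s.periods)
        a = evaluate(s, tiny_sim_config, c, replications=2, seed=4)
        b = evaluate(s, tiny_sim_config, c, replications=2, seed=4)
        assert a == b

    def test_zero_cost_model(self, tiny_sim_config):
        s = self._schedule()
        c = CostModel.unit(s.kinds, s.periods, cost=0.0)
        z_cost, _ = evaluate(s, tiny_sim_config, c, replications=1, seed=0)
        assert z_cost == 0.0

    def test_infeasible_rejected_without_simulation(self, tiny_sim_config):
        s = self._schedule()
        c = CostModel.unit(s.kinds, s.periods)
        with pytest.raises(ValueError, match="rejected"):
            evaluate(s, tiny_sim_config, c, replications=1, seed=0, A=2)
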