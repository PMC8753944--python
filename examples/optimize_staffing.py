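"""Optimize staffing with the simulation in the loop.

The bundled default load barely queues, so this demo runs a deliberately
overloaded morning (arrival gaps scaled down, tickets until 09:00) where the
number of counters genuinely moves both objectives.  The two single-objective
searches anchor the fuzzy memberships; a weighted max-min search with weights
(0.5, 0.5) then trades cost against satisfaction.  Unit cost coefficients
stand in for the department's private salary data.
"""

import dataclasses

import numpy as np

from hospflow import (
    ArrivalSegment,
    MultiObjective,
    SearchConfig,
    SearchSpace,
    SingleObjective,
    WeightSet,
    bounds_from_single_objective,
    default_config,
    search,
    simulation_evaluator,
)
from hospflow.staffing import CostModel

base = dataclasses.replace(
    default_config(),
    arrival_segments=[
        ArrivalSegment(0.0, 60.0, 0.0, 2.0),
        ArrivalSegment(60.0, 600.0, 0.1, 0.4),
    ],
    ticket_close=240.0,  # 09:00 — a crowded morning, then the queues drain
)

kinds = ("N", "N2", "M1", "M2", "M3", "M4")
periods = ("07-09", "09-11", "11-13", "13-15")
space = SearchSpace(
    kinds=kinds,
    periods=periods,
    lower=np.ones((len(kinds), len(periods)), dtype=int),
    upper=np.tile([[4], [3], [3], [3], [3], [6]], (1, len(periods))),
    A=12,
)
cost_model = CostModel.unit(kinds, periods, cost=100.0)
evaluator = simulation_evaluator(base, cost_model, replications=2, seed=7)
stop = SearchConfig(stop_after_non_improving=25, seed=11)

cost_run = search(SingleObjective("cost"), space, evaluator, stop)
sat_run = search(SingleObjective("satisfaction"), space, evaluator, stop)
print(f"min-cost run:         Z_cost={cost_run.z_cost:7.1f}  Z_sat={cost_run.z_sat:6.2f}%")
print(f"max-satisfaction run: Z_cost={sat_run.z_cost:7.1f}  Z_sat={sat_run.z_sat:6.2f}%")

bounds = bounds_from_single_objective(cost_run, sat_run)
objective = MultiObjective(WeightSet(0.5, 0.5), bounds["cost"], bounds["satisfaction"])
multi = search(objective, space, evaluator, stop)
print(
    f"weighted max-min (0.5, 0.5): lambda={multi.lam:.3f}  "
    f"Z_cost={multi.z_cost:7.1f}  Z_sat={multi.z_sat:6.2f}%  "
    f"({multi.evaluations} schedules evaluated)"
)
print("chosen staffing (rows = resource kinds, columns = periods):")
print(multi.best_schedule.to_frame().to_string())
print(
    "\nlambda is the common degree to which both weighted objectives reach "
    "their optimistic anchors; the compromise sits between the cheap/"
    "impatient and expensive/satisfied extremes."
)
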