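"""Staffing optimization: cost objective, fuzzy normalization, weighted
max-min achievement level, and a simulation-driven heuristic search.

Two objectives are considered over integer staffing schedules n_{i,t}:

* Z_cost = Sum_t Sum_i c_{i,t} n_{i,t}  (Baht/day, minimized);
* Z_sat  = mean patient satisfaction score over the day (%, maximized);

subject to Sum_{MR kinds} n_{i,t} <= A in every period and n_{i,t}
nonnegative integers.

For the multi-objective problem each objective value is normalized onto
[0, 1] between its optimistic (Z+) and pessimistic (Z-) extremes — obtained
by optimizing each objective on its own — and the weighted max-min
achievement level

    lambda = max { l in [0,1] : w_k * l <= f_k for every objective k }

is maximized, i.e. lambda = min(1, min_k f_k / w_k).

The search itself is a black-box heuristic in the spirit of commercial
scatter-search optimizers: randomized +-1 neighborhood moves with periodic
uniform restarts, rejecting infeasible candidates without simulating them,
and stopping after a fixed number of consecutive evaluated candidates with
no improvement (default 100).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

from .rng import child_seed, substream
from .satisfaction import average_satisfaction
from .staffing import CostModel, ResourceSchedule

__all__ = [
    "WeightSet",
    "DEFAULT_WEIGHT_SETS",
    "ObjectiveBounds",
    "SingleObjective",
    "MultiObjective",
    "SearchSpace",
    "SearchConfig",
    "OptimizationResult",
    "operating_cost",
    "feasible",
    "evaluate",
    "membership",
    "lambda_level",
    "search",
    "bounds_from_single_objective",
    "simulation_evaluator",
]


@dataclass(frozen=True)
class WeightSet:
    """Objective priorities (w_cost, w_sat), summing to one."""

    w_cost: float
    w_sat: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_cost <= 1.0 and 0.0 <= self.w_sat <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.w_cost + self.w_sat - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


#: Sensitivity-analysis weight settings used throughout the case study.
DEFAULT_WEIGHT_SETS: tuple[WeightSet, ...] = (
    WeightSet(0.8, 0.2),
    WeightSet(0.2, 0.8),
    WeightSet(0.6, 0.4),
    WeightSet(0.4, 0.6),
    WeightSet(0.5, 0.5),
)


@dataclass(frozen=True)
class ObjectiveBounds:
    """Fuzzy normalization anchors for one objective.

    ``z_plus`` is the anchor written Z+ in the max-min model and ``z_minus``
    is Z-; for a min-sense objective Z- is the optimistic (small) extreme,
    for a max-sense objective Z+ is the optimistic (large) extreme.
    """

    z_plus: float
    z_minus: float
    sense: str  # 'min' | 'max'

    def __post_init__(self) -> None:
        if self.sense not in ("min", "max"):
            raise ValueError("objective sense must be 'min' or 'max'")
        if self.z_plus == self.z_minus:
            raise ValueError("degenerate bounds: Z+ equals Z-")


def operating_cost(schedule: ResourceSchedule, cost_model: CostModel) -> float:
    """Total daily operating cost Sum_t Sum_i c_{i,t} n_{i,t} (Baht/day).

    Linear and nondecreasing in every staffing level.
    """
    if schedule.kinds != cost_model.kinds or schedule.periods != cost_model.periods:
        raise ValueError(
            "schedule and cost model must cover the same kinds and periods"
        )
    return float((cost_model.c * schedule.n).sum())


def feasible(schedule: ResourceSchedule, A: int) -> bool:
    """True iff total MR-counter staffing is at most A in every period.

    Nonnegativity and integrality are enforced by ``ResourceSchedule``
    itself; raw matrices are also accepted and checked here.
    """
    if not isinstance(schedule, ResourceSchedule):
        n = np.asarray(schedule)
        if (n < 0).any() or not np.allclose(n, np.round(n)):
            return False
        return True
    return bool((schedule.mr_totals() <= A).all())


def evaluate(
    schedule: ResourceSchedule,
    sim_config,
    cost_model: CostModel,
    replications: int = 8,
    seed: int = 0,
    A: int | None = None,
) -> tuple[float, float]:
    """(Z_cost, Z_sat) for one staffing schedule.

    Z_cost is deterministic; Z_sat is the mean over ``replications``
    simulated days of the day's average satisfaction score.  Identical
    (schedule, seed) pairs give identical results.  An infeasible schedule
    is rejected without running the simulation.
    """
    from .flow import simulate_day  # deferred: flow is a heavier import

    if A is not None and not feasible(schedule, A):
        raise ValueError("infeasible schedule rejected without simulation")
    z_cost = operating_cost(schedule, cost_model)
    config = replace(sim_config, schedule=schedule)
    sats = []
    for r in range(replications):
        record = simulate_day(config, child_seed(seed, r))
        sats.append(average_satisfaction(record.patients))
    return z_cost, float(np.mean(sats))


def simulation_evaluator(
    sim_config, cost_model: CostModel, replications: int = 8, seed: int = 0
) -> Callable[[ResourceSchedule], tuple[float, float]]:
    """Bind :func:`evaluate` into the (schedule) -> (Z_cost, Z_sat) form the
    search consumes.  Common random numbers: every candidate sees the same
    replication seeds."""

    def _eval(schedule: ResourceSchedule) -> tuple[float, float]:
        return evaluate(schedule, sim_config, cost_model, replications, seed)

    return _eval


def membership(z: float, bounds: ObjectiveBounds) -> float:
    """Fuzzy membership f in [0, 1] of an objective value.

    min-sense: (Z+ - Z) / (Z+ - Z-);  max-sense: (Z - Z-) / (Z+ - Z-).
    Equals 1 at the optimistic extreme and 0 at the pessimistic one.  Values
    outside [Z-, Z+] — possible when the anchors come from separate
    stochastic runs — are clipped into [0, 1].
    """
    span = bounds.z_plus - bounds.z_minus
    if bounds.sense == "min":
        f = (bounds.z_plus - z) / span
    else:
        f = (z - bounds.z_minus) / span
    return float(min(1.0, max(0.0, f)))


def lambda_level(memberships: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted max-min achievement level.

    The largest lambda in [0, 1] with w_k * lambda <= f_k for every
    objective: lambda = min(1, min_{w_k > 0} f_k / w_k).  Zero-weight
    objectives impose no constraint.
    """
    if len(memberships) != len(weights):
        raise ValueError("one weight per membership required")
    for f in memberships:
        if not 0.0 <= f <= 1.0 + 1e-12:
            raise ValueError(f"membership {f} outside [0, 1]")
    ratios = [f / w for f, w in zip(memberships, weights) if w > 0.0]
    if not ratios:
        return 1.0
    return float(min(1.0, min(ratios)))


@dataclass(frozen=True)
class SingleObjective:
    """Optimize one objective on its own: 'cost' (min) or 'satisfaction' (max)."""

    target: str

    def __post_init__(self) -> None:
        if self.target not in ("cost", "satisfaction"):
            raise ValueError("target must be 'cost' or 'satisfaction'")


@dataclass(frozen=True)
class MultiObjective:
    """Weighted max-min over the two fuzzy-normalized objectives."""

    weights: WeightSet
    cost_bounds: ObjectiveBounds
    sat_bounds: ObjectiveBounds


@dataclass(eq=False)
class SearchSpace:
    """Integer box bounds on every staffing entry, plus the MR capacity A."""

    kinds: tuple[str, ...]
    periods: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    A: int

    def __post_init__(self) -> None:
        self.kinds = tuple(self.kinds)
        self.periods = tuple(self.periods)
        self.lower = np.asarray(self.lower, dtype=int)
        self.upper = np.asarray(self.upper, dtype=int)
        shape = (len(self.kinds), len(self.periods))
        if self.lower.shape != shape or self.upper.shape != shape:
            raise ValueError("bounds must match kinds x periods")
        if (self.lower < 0).any() or (self.lower > self.upper).any():
            raise ValueError("need 0 <= lower <= upper")

    def schedule(self, n: np.ndarray) -> ResourceSchedule:
        return ResourceSchedule(kinds=self.kinds, periods=self.periods, n=n)

    def is_feasible(self, n: np.ndarray) -> bool:
        if (n < self.lower).any() or (n > self.upper).any():
            return False
        return feasible(self.schedule(n), self.A)

    def enumerate(self) -> Iterator[np.ndarray]:
        """Every lattice point inside the box, row-major (may be huge — meant
        for small instances and exhaustive search)."""
        ranges = [
            range(int(lo), int(hi) + 1)
            for lo, hi in zip(self.lower.ravel(), self.upper.ravel())
        ]
        shape = self.lower.shape
        for combo in itertools.product(*ranges):
            yield np.array(combo, dtype=int).reshape(shape)

    def size(self) -> int:
        return int(np.prod(self.upper - self.lower + 1, dtype=float))

    def random_point(self, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(self.lower, self.upper + 1)

    def neighbor(self, n: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """+-1 on one uniformly chosen entry, clipped to the box."""
        out = n.copy()
        flat = out.ravel()
        i = int(rng.integers(flat.size))
        step = 1 if rng.random() < 0.5 else -1
        flat[i] = int(np.clip(flat[i] + step, self.lower.ravel()[i], self.upper.ravel()[i]))
        return out


@dataclass
class SearchConfig:
    """Stopping rule and proposal strategy for the heuristic search."""

    stop_after_non_improving: int = 100
    replications_per_eval: int = 8
    seed: int = 0
    proposal: str = "neighborhood"  # or 'exhaustive'
    restart_prob: float = 0.1
    max_feasibility_tries: int = 100_000

    def __post_init__(self) -> None:
        if self.stop_after_non_improving < 1:
            raise ValueError("stop_after_non_improving must be >= 1")
        if self.proposal not in ("neighborhood", "exhaustive"):
            raise ValueError("proposal must be 'neighborhood' or 'exhaustive'")


@dataclass
class OptimizationResult:
    best_schedule: ResourceSchedule
    z_cost: float
    z_sat: float
    lam: float | None
    evaluations: int
    trace: list[dict] = field(repr=False, default_factory=list)


def _score(objective, z_cost: float, z_sat: float) -> tuple[float, float | None]:
    """(maximized scalar, lambda-or-None) for a candidate's objective values."""
    if isinstance(objective, SingleObjective):
        return (-z_cost, None) if objective.target == "cost" else (z_sat, None)
    if isinstance(objective, MultiObjective):
        f_cost = membership(z_cost, objective.cost_bounds)
        f_sat = membership(z_sat, objective.sat_bounds)
        lam = lambda_level(
            (f_cost, f_sat), (objective.weights.w_cost, objective.weights.w_sat)
        )
        return lam, lam
    raise TypeError(f"unknown objective specification {objective!r}")


def search(
    objective,
    space: SearchSpace,
    evaluate_fn: Callable[[ResourceSchedule], tuple[float, float]],
    config: SearchConfig | None = None,
) -> OptimizationResult:
    """Heuristic search over the feasible staffing lattice.

    Proposes candidates (randomized neighborhood moves with uniform restarts,
    or exhaustive enumeration), rejects infeasible ones without evaluating,
    and stops after ``stop_after_non_improving`` consecutive evaluated
    candidates without improvement of the incumbent.  Every candidate is
    logged in the trace.  With exhaustive proposal and a stopping patience at
    least the lattice size this degenerates to brute-force enumeration.
    """
    config = config or SearchConfig()
    rng = substream(config.seed, "optimizer")
    cache: dict[tuple, tuple[float, float]] = {}
    trace: list[dict] = []
    evaluations = 0

    def run_eval(n: np.ndarray) -> tuple[float, float]:
        key = tuple(n.ravel().tolist())
        if key not in cache:
            cache[key] = evaluate_fn(space.schedule(n))
        return cache[key]

    proposals: Iterator[np.ndarray]
    if config.proposal == "exhaustive":
        proposals = space.enumerate()
    else:
        proposals = None  # drawn adaptively below

    # first feasible incumbent
    incumbent = None
    if config.proposal == "exhaustive":
        for cand in proposals:
            if space.is_feasible(cand):
                incumbent = cand
                break
        else:
            raise ValueError("empty feasible region")
    else:
        lower_corner = space.lower.copy()
        if space.is_feasible(lower_corner):
            incumbent = lower_corner
        else:
            for _ in range(config.max_feasibility_tries):
                cand = space.random_point(rng)
                if space.is_feasible(cand):
                    incumbent = cand
                    break
            if incumbent is None:
                raise ValueError(
                    "no feasible schedule found within "
                    f"{config.max_feasibility_tries} random tries"
                )

    z_cost, z_sat = run_eval(incumbent)
    evaluations += 1
    best_score, best_lam = _score(objective, z_cost, z_sat)
    best = (incumbent, z_cost, z_sat, best_lam)
    trace.append(
        {"candidate": tuple(incumbent.ravel().tolist()), "feasible": True,
         "z_cost": z_cost, "z_sat": z_sat, "score": best_score, "improved": True}
    )

    non_improving = 0
    while non_improving < config.stop_after_non_improving:
        if config.proposal == "exhaustive":
            try:
                cand = next(proposals)
            except StopIteration:
                break
        else:
            if rng.random() < config.restart_prob:
                cand = space.random_point(rng)
            else:
                cand = space.neighbor(best[0], rng)
        if not space.is_feasible(cand):
            trace.append(
                {"candidate": tuple(cand.ravel().tolist()), "feasible": False}
            )
            continue
        z_cost, z_sat = run_eval(cand)
        evaluations += 1
        score, lam = _score(objective, z_cost, z_sat)
        improved = score > best_score + 1e-12
        trace.append(
            {"candidate": tuple(cand.ravel().tolist()), "feasible": True,
             "z_cost": z_cost, "z_sat": z_sat, "score": score, "improved": improved}
        )
        if improved:
            best_score = score
            best = (cand, z_cost, z_sat, lam)
            non_improving = 0
        else:
            non_improving += 1

    n_best, z_cost, z_sat, lam = best
    return OptimizationResult(
        best_schedule=space.schedule(n_best),
        z_cost=z_cost,
        z_sat=z_sat,
        lam=lam,
        evaluations=evaluations,
        trace=trace,
    )


def bounds_from_single_objective(
    cost_result: OptimizationResult, sat_result: OptimizationResult
) -> dict[str, ObjectiveBounds]:
    """Fuzzy anchors from the two single-objective runs.

    The cost-minimizing run supplies the optimistic cost (Z-) and the
    pessimistic satisfaction (Z-); the satisfaction-maximizing run supplies
    the pessimistic cost (Z+) and the optimistic satisfaction (Z+).
    """
    if cost_result.z_cost == sat_result.z_cost:
        raise ValueError("degenerate cost bounds: both runs reached the same cost")
    if cost_result.z_sat == sat_result.z_sat:
        raise ValueError(
            "degenerate satisfaction bounds: both runs reached the same score"
        )
    return {
        "cost": ObjectiveBounds(
            z_plus=sat_result.z_cost, z_minus=cost_result.z_cost, sense="min"
        ),
        "satisfaction": ObjectiveBounds(
            z_plus=sat_result.z_sat, z_minus=cost_result.z_sat, sense="max"
        ),
    }
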