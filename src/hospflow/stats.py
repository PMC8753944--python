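"""Verification, validation, replication sizing, scenario comparison and the
decision guidelines.

* **Verification** — a deterministic, queue-free run (one patient per type,
  service times at their means, ample capacity) must reproduce the hand
  summation of mean service times along each type's path, exactly.
* **Validation** — Welch's two-sided t-test of simulated mean LOS against
  reference statistics collected in the real department.
* **Replication sizing** — the half-width of the pilot 95% CI, projected as
  1/sqrt(n), gives the number of replications meeting a relative-error
  target.
* **Comparison** — blocked two-factor ANOVA (case x scenario, replication as
  block) on per-replication mean satisfaction, followed by Tukey HSD with a
  compact letter display.
* **Decision** — a nine-row guideline mapping (satisfaction change, cost
  change) vs. the unoptimized benchmark to a recommendation, plus the
  case-selection procedure driven by a minimum acceptable score.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .flow import PATIENT_TYPES, flow_path, mean_service, simulate_day
from .staffing import ResourceSchedule

__all__ = [
    "SampleSummary",
    "TTestResult",
    "VerificationReport",
    "ReplicationSizing",
    "DecisionOutcome",
    "verify",
    "welch_t",
    "validate_against_reference",
    "required_replications",
    "anova_blocked",
    "tukey_pairwise",
    "tukey_letters",
    "classify_decision",
    "select_case",
]


# ---------------------------------------------------------------------------
# verification


@dataclass(frozen=True)
class VerificationReport:
    """Per-type manual vs. simulated LOS under the deterministic no-queue run."""

    manual_los: dict[int, float]
    simulated_los: dict[int, float]
    tolerance: float = 1e-9

    @property
    def equal(self) -> dict[int, bool]:
        return {
            t: abs(self.manual_los[t] - self.simulated_los[t]) < self.tolerance
            for t in self.manual_los
        }

    @property
    def all_equal(self) -> bool:
        return all(self.equal.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_type": list(self.manual_los),
                "manual_los_min": [self.manual_los[t] for t in self.manual_los],
                "simulated_los_min": [self.simulated_los[t] for t in self.manual_los],
                "equal": [self.equal[t] for t in self.manual_los],
            }
        )


def _ample_schedule(policy: str) -> ResourceSchedule:
    kinds = ("N", "N2", "M") if policy == "one_stop" else ("N", "N2", "M1", "M2", "M3", "M4")
    return ResourceSchedule.uniform({k: 99 for k in kinds})


def verify(config) -> VerificationReport:
    """Deterministic no-queue equivalence check.

    Runs one old-status patient of each type alone through the model with
    service times fixed at their means and ample capacity, and compares the
    simulated LOS with the manual sum of mean service times along the type's
    path (both in minutes).  Any mismatch flags a model bug.
    """
    manual: dict[int, float] = {}
    simulated: dict[int, float] = {}
    base = replace(config, schedule=_ample_schedule(config.policy))
    for t in PATIENT_TYPES:
        path = flow_path(t, is_new=False)
        manual[t] = sum(
            mean_service(config.services[f"mr_type{t}" if s == "mr" else s])
            for s in path
        ) / 60.0
        record = simulate_day(
            replace(base, forced_arrivals=[(0.0, t, False)]),
            seed=0,
            deterministic=True,
        )
        simulated[t] = record.patients[0].los
    return VerificationReport(manual_los=manual, simulated_los=simulated)


# ---------------------------------------------------------------------------
# validation (Welch's t-test on summary statistics)


@dataclass(frozen=True)
class SampleSummary:
    """(mean, sd, n) summary of one LOS sample, minutes."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float

    @property
    def reject_at_95(self) -> bool:
        return self.p_value < 0.05


def welch_t(a: SampleSummary, b: SampleSummary) -> TTestResult:
    """Two-sided unequal-variance (Welch) t-test from summary statistics.

    Hand-computed Welch-Satterthwaite formula; both-degenerate samples with
    equal means return p = 1 by convention.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0.0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=float(a.n + b.n - 2), p_value=1.0)
        return TTestResult(t=math.inf, df=float(a.n + b.n - 2), p_value=0.0)
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p_value=float(p))


def validate_against_reference(
    los_by_type: Mapping[int, Sequence[float]],
    reference: Mapping[int, SampleSummary],
) -> dict[int, TTestResult]:
    """Welch-test simulated LOS samples against per-type reference stats.

    No rejection at the 95% level means the model is consistent with the
    observed system for that patient type.
    """
    out = {}
    for t, values in los_by_type.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"type {t}: need at least 2 simulated values")
        sim = SampleSummary(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))
        out[t] = welch_t(reference[t], sim)
    return out


# ---------------------------------------------------------------------------
# replication sizing


@dataclass(frozen=True)
class ReplicationSizing:
    n0: int
    mean: float
    half_width: float
    relative_error: float
    required_n: int


def required_replications(
    pilot_values: Sequence[float], target_relative_error: float = 0.05
) -> ReplicationSizing:
    """Replications needed for a 95% CI half-width within a relative target.

    The pilot half-width uses the t-based CI; the projection assumes the
    half-width shrinks as 1/sqrt(n), so required_n = ceil(n0 * (rel/target)^2)
    when the pilot misses the target, and stays at the pilot size otherwise.
    """
    if target_relative_error <= 0:
        raise ValueError("target relative error must be positive")
    values = np.asarray(list(pilot_values), dtype=float)
    n0 = values.size
    if n0 < 2:
        raise ValueError("pilot needs at least 2 replications")
    mean = float(values.mean())
    if mean == 0.0:
        raise ValueError("relative error undefined for zero mean")
    sd = float(values.std(ddof=1))
    hw = float(sps.t.ppf(0.975, n0 - 1) * sd / math.sqrt(n0))
    rel = abs(hw / mean)
    if rel <= target_relative_error:
        required = n0
    else:
        # epsilon guards the ceiling against float round-off at exact ratios
        required = int(math.ceil(n0 * (rel / target_relative_error) ** 2 - 1e-9))
    return ReplicationSizing(
        n0=int(n0), mean=mean, half_width=hw, relative_error=rel, required_n=required
    )


# ---------------------------------------------------------------------------
# blocked ANOVA


_ANOVA_ROWS = {
    "C(case)": "Case",
    "C(scenario)": "Scenario",
    "C(replication)": "Replication",
    "C(case):C(scenario)": "Case*Scenario",
    "Residual": "Error",
}


def anova_blocked(responses: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects ANOVA: Case + Scenario + Replication (block) +
    Case x Scenario interaction.

    ``responses`` must be a complete crossed layout with columns ``case``,
    ``scenario``, ``replication`` and ``response`` (per-replication mean
    satisfaction).  Returns a table with rows Case, Scenario, Replication,
    Case*Scenario, Error, Total and columns DF, adj SS, adj MS, F, p.  With a
    constant response every F is reported as 0 with p = 1.
    """
    df = responses.copy()
    required = {"case", "scenario", "replication", "response"}
    if not required.issubset(df.columns):
        raise ValueError(f"responses must have columns {sorted(required)}")
    counts = df.groupby(["case", "scenario", "replication"]).size()
    n_cells = df["case"].nunique() * df["scenario"].nunique() * df["replication"].nunique()
    if len(counts) != n_cells or (counts != 1).any():
        raise ValueError("incomplete layout: need exactly one response per "
                         "case x scenario x replication cell")

    constant_response = float(df["response"].var(ddof=0)) < 1e-12
    model = smf.ols(
        "response ~ C(case) + C(scenario) + C(replication) + C(case):C(scenario)",
        data=df,
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)

    rows = []
    for src, label in _ANOVA_ROWS.items():
        ss = float(table.loc[src, "sum_sq"])
        dfree = float(table.loc[src, "df"])
        ms = ss / dfree if dfree > 0 else math.nan
        if label == "Error":
            f_val, p_val = math.nan, math.nan
        else:
            f_val = float(table.loc[src, "F"])
            p_val = float(table.loc[src, "PR(>F)"])
            if constant_response or math.isnan(f_val):
                # no variance to explain; numerical noise in the fit aside
                f_val, p_val = 0.0, 1.0
        rows.append({"source": label, "DF": int(dfree), "adj_SS": ss,
                     "adj_MS": ms, "F": f_val, "p": p_val})
    total_ss = sum(r["adj_SS"] for r in rows)
    rows.append({"source": "Total", "DF": len(df) - 1, "adj_SS": total_ss,
                 "adj_MS": math.nan, "F": math.nan, "p": math.nan})
    out = pd.DataFrame(rows).set_index("source")
    assert out.loc["Total", "DF"] == sum(
        out.loc[s, "DF"] for s in out.index if s != "Total"
    ), "ANOVA degrees of freedom must sum to the total"
    return out


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display


def _pair_se(mse: float, n_i: float, n_j: float) -> float:
    # Tukey-Kramer standard error; reduces to sqrt(mse/n) for equal n.
    return math.sqrt(mse / 2.0 * (1.0 / n_i + 1.0 / n_j))


def tukey_pairwise(
    means: Mapping, mse: float, df_error: int, n, alpha: float = 0.05
) -> dict[tuple, dict]:
    """All pairwise Tukey HSD comparisons on cell means.

    ``n`` is the per-group replication count (scalar or mapping).  Returns,
    per unordered pair, the studentized-range statistic q, its p-value, and
    the significance decision at ``alpha`` (family-wise).
    """
    keys = list(means)
    k = len(keys)
    n_of = (lambda g: n[g]) if isinstance(n, Mapping) else (lambda g: n)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = keys[i], keys[j]
            se = _pair_se(mse, n_of(gi), n_of(gj))
            q = abs(means[gi] - means[gj]) / se if se > 0 else math.inf
            p = float(sps.studentized_range.sf(q, k, df_error)) if math.isfinite(q) else 0.0
            out[(gi, gj)] = {"q": q, "p": p, "significant": p < alpha}
    return out


def tukey_letters(
    means: Mapping, mse: float, df_error: int, n, alpha: float = 0.05
) -> dict:
    """Compact letter display for Tukey HSD groupings.

    Two means share a letter if and only if they are *not* significantly
    different at the family-wise ``alpha``.  Uses the insert-and-absorb
    construction: start from one column holding every group, split a column
    for each significant pair it contains, then drop columns that became
    subsets of others.  Letters are ordered by the best-ranked member of each
    column, so 'A' always contains the largest mean.
    """
    keys = sorted(means, key=lambda g: -means[g])
    if len(keys) == 1:
        return {keys[0]: "A"}
    pairwise = tukey_pairwise(means, mse, df_error, n, alpha)

    columns: list[set] = [set(keys)]
    for (gi, gj), res in pairwise.items():
        if not res["significant"]:
            continue
        new_columns = []
        for col in columns:
            if gi in col and gj in col:
                new_columns.extend((col - {gi}, col - {gj}))
            else:
                new_columns.append(col)
        # absorb: remove any column contained in another
        columns = [
            c for c in new_columns
            if not any(c < other for other in new_columns)
        ]
        # deduplicate while preserving order
        seen, uniq = [], []
        for c in columns:
            if c not in seen:
                seen.append(c)
                uniq.append(c)
        columns = uniq

    columns.sort(key=lambda col: min(keys.index(g) for g in col))
    if len(columns) > len(string.ascii_uppercase):
        raise ValueError("more letter groups than letters available")
    letters = {g: "" for g in keys}
    for letter, col in zip(string.ascii_uppercase, columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in keys}


# ---------------------------------------------------------------------------
# decision guidelines


@dataclass(frozen=True)
class DecisionOutcome:
    satisfaction_change: str  # 'higher' | 'unchanged' | 'lower'
    cost_change: str
    suggestion: str  # 'recommended' | 'not_recommended' | 'depends_on_decision_maker'
    remark: str


_GUIDELINES: dict[tuple[str, str], tuple[str, str]] = {
    ("higher", "higher"): (
        "depends_on_decision_maker",
        "Satisfaction improves; accept if the extra cost is tolerable.",
    ),
    ("higher", "unchanged"): (
        "recommended",
        "Satisfaction improves at the same cost.",
    ),
    ("higher", "lower"): (
        "recommended",
        "Satisfaction improves and the cost drops.",
    ),
    ("unchanged", "higher"): (
        "not_recommended",
        "Extra spending with no satisfaction gain.",
    ),
    ("unchanged", "unchanged"): (
        "depends_on_decision_maker",
        "Neither factor moves; weigh secondary criteria such as staff workload.",
    ),
    ("unchanged", "lower"): (
        "recommended",
        "Same satisfaction at a lower cost.",
    ),
    ("lower", "higher"): (
        "not_recommended",
        "Worse on both counts.",
    ),
    ("lower", "unchanged"): (
        "not_recommended",
        "Satisfaction drops with no saving.",
    ),
    ("lower", "lower"): (
        "depends_on_decision_maker",
        "Cheaper but less satisfying; acceptable if the drop is tolerable.",
    ),
}


def classify_decision(sat_change: str, cost_change: str) -> DecisionOutcome:
    """The nine-row guideline: (satisfaction change, cost change) vs. the
    benchmark -> recommendation.  Total and deterministic over the 3 x 3
    grid."""
    key = (sat_change, cost_change)
    if key not in _GUIDELINES:
        raise ValueError(
            "changes must be 'higher', 'unchanged' or 'lower' "
            f"(got {sat_change!r}, {cost_change!r})"
        )
    suggestion, remark = _GUIDELINES[key]
    return DecisionOutcome(sat_change, cost_change, suggestion, remark)


def compare_to_benchmark(table: pd.DataFrame, benchmark: pd.Series) -> pd.DataFrame:
    """Classify every comparison row against the benchmark row.

    Satisfaction is 'unchanged' when the row shares at least one Tukey letter
    with the benchmark; 'higher'/'lower' otherwise by its mean.  Cost changes
    compare exactly (costs are deterministic).
    """
    bench_letters = set(benchmark["letters"])
    rows = []
    for _, row in table.iterrows():
        if set(row["letters"]) & bench_letters:
            sat = "unchanged"
        else:
            sat = "higher" if row["mean"] > benchmark["mean"] else "lower"
        if row["cost"] == benchmark["cost"]:
            cost = "unchanged"
        else:
            cost = "higher" if row["cost"] > benchmark["cost"] else "lower"
        outcome = classify_decision(sat, cost)
        rows.append(
            {**row, "sat_change": sat, "cost_change": cost,
             "suggestion": outcome.suggestion}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# case selection


@dataclass(frozen=True)
class SelectedCase:
    scenario: object
    case: object
    cost: float
    mean: float
    letters: str


def select_case(min_acceptable_score: float, table: pd.DataFrame) -> SelectedCase:
    """Pick the scenario/case meeting a minimum satisfaction score cheaply.

    1. Find the letter group whose span of means contains the threshold (or,
       failing that, the group nearest above it).
    2. Take the cheapest row of that group.
    3. If any row of a strictly higher-scoring group is cheaper, take the
       cheapest such row instead.

    ``table`` needs columns scenario, case, cost, mean, letters.  A threshold
    above every mean is an error — no case is feasible.
    """
    if table.empty:
        raise ValueError("empty comparison table")
    letter_span: dict[str, tuple[float, float]] = {}
    for _, row in table.iterrows():
        for letter in row["letters"]:
            lo, hi = letter_span.get(letter, (math.inf, -math.inf))
            letter_span[letter] = (min(lo, row["mean"]), max(hi, row["mean"]))

    containing = [
        L for L, (lo, hi) in letter_span.items() if lo <= min_acceptable_score <= hi
    ]
    if containing:
        # group with the highest span if the threshold sits in an overlap
        chosen_letter = max(containing, key=lambda L: letter_span[L][1])
    else:
        above = [L for L, (lo, _) in letter_span.items() if lo >= min_acceptable_score]
        if not above:
            raise ValueError(
                f"no feasible case: threshold {min_acceptable_score} exceeds "
                "every satisfaction mean"
            )
        chosen_letter = min(above, key=lambda L: letter_span[L][0])

    group_rows = table[table["letters"].str.contains(chosen_letter)]
    pick = group_rows.loc[group_rows["cost"].idxmin()]

    def is_higher_group(letters: str) -> bool:
        return chosen_letter not in letters and min(letters) < chosen_letter

    higher = table[table["letters"].map(is_higher_group)]
    if not higher.empty:
        cheaper = higher[higher["cost"] < pick["cost"]]
        if not cheaper.empty:
            pick = cheaper.loc[cheaper["cost"].idxmin()]

    return SelectedCase(
        scenario=pick["scenario"],
        case=pick["case"],
        cost=float(pick["cost"]),
        mean=float(pick["mean"]),
        letters=str(pick["letters"]),
    )
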