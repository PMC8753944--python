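"""Integer staffing schedules and per-period operating-cost coefficients.

Resource kinds follow the front-end department's staffing legend:

========  =====================================================
``N``     triage nurse serving type-1 patients
``N2``    triage nurse serving type-2 patients
``M``     pooled medical-record (MR) operator (one-stop policy)
``M1``    MR operator serving type-1 patients
``M12``   MR operator serving type-1 and type-2 patients
``M2``    MR operator serving type-2 patients
``M3``    MR operator serving type-3 patients
``M4``    MR operator serving type-4 patients
========  =====================================================

Staffing varies over two-hour periods.  Schedules may cover four periods
(07-09 through 13-15), in which case the first period's levels also apply
from the 05:00 opening, or all five.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RESOURCE_KINDS",
    "MR_KINDS",
    "PERIOD_STARTS",
    "ResourceSchedule",
    "CostModel",
]

RESOURCE_KINDS: tuple[str, ...] = ("N", "N2", "M", "M1", "M12", "M2", "M3", "M4")
#: The kinds counted against the total MR-counter capacity A.
MR_KINDS: tuple[str, ...] = ("M", "M1", "M12", "M2", "M3", "M4")
#: Period label -> start minute (since the 05:00 opening).
PERIOD_STARTS: dict[str, float] = {
    "05-07": 0.0,
    "07-09": 120.0,
    "09-11": 240.0,
    "11-13": 360.0,
    "13-15": 480.0,
}


@dataclass(eq=False)
class ResourceSchedule:
    """The optimizer's decision variable: integer servers per kind x period."""

    kinds: tuple[str, ...]
    periods: tuple[str, ...]
    n: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.kinds = tuple(self.kinds)
        self.periods = tuple(self.periods)
        for k in self.kinds:
            if k not in RESOURCE_KINDS:
                raise ValueError(f"unknown resource kind {k!r}")
        for p in self.periods:
            if p not in PERIOD_STARTS:
                raise ValueError(f"unknown staffing period {p!r}")
        if list(self.periods) != sorted(self.periods, key=PERIOD_STARTS.get):
            raise ValueError("staffing periods must be in chronological order")
        n = np.asarray(self.n)
        if n.shape != (len(self.kinds), len(self.periods)):
            raise ValueError(
                f"staffing matrix shape {n.shape} does not match "
                f"{len(self.kinds)} kinds x {len(self.periods)} periods"
            )
        if not np.issubdtype(n.dtype, np.integer):
            if not np.allclose(n, np.round(n)):
                raise ValueError("staffing levels must be integers")
            n = np.round(n).astype(int)
        if (n < 0).any():
            raise ValueError("staffing levels must be nonnegative")
        self.n = n.astype(int)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_rows(cls, rows: dict[str, list[int]], periods: tuple[str, ...]) -> "ResourceSchedule":
        kinds = tuple(rows)
        n = np.array([rows[k] for k in kinds], dtype=int)
        return cls(kinds=kinds, periods=tuple(periods), n=n)

    @classmethod
    def uniform(cls, levels: dict[str, int],
                periods: tuple[str, ...] = ("07-09", "09-11", "11-13", "13-15")
                ) -> "ResourceSchedule":
        """Same staffing level in every period."""
        return cls.from_rows({k: [v] * len(periods) for k, v in levels.items()}, periods)

    # -- access ------------------------------------------------------------

    def level(self, kind: str, period: str) -> int:
        return int(self.n[self.kinds.index(kind), self.periods.index(period)])

    def capacity_breakpoints(self, kind: str) -> list[tuple[float, int]]:
        """(start minute, capacity) breakpoints for a resource kind.

        A schedule starting at 07-09 is extended back to the 05:00 opening at
        its first period's level; the last period's level holds until the
        queues empty.  A kind absent from the schedule has zero capacity.
        """
        if kind not in self.kinds:
            return [(0.0, 0)]
        row = self.n[self.kinds.index(kind)]
        points = [(PERIOD_STARTS[p], int(c)) for p, c in zip(self.periods, row)]
        if points[0][0] > 0.0:
            points.insert(0, (0.0, points[0][1]))
        return points

    def mr_totals(self) -> np.ndarray:
        """Total MR-counter staffing per period (the Sum n_i,t of the capacity
        constraint)."""
        idx = [i for i, k in enumerate(self.kinds) if k in MR_KINDS]
        if not idx:
            return np.zeros(len(self.periods), dtype=int)
        return self.n[idx].sum(axis=0)

    def with_entry(self, kind: str, period: str, value: int) -> "ResourceSchedule":
        n = self.n.copy()
        n[self.kinds.index(kind), self.periods.index(period)] = value
        return ResourceSchedule(kinds=self.kinds, periods=self.periods, n=n)

    # -- equality / io -----------------------------------------------------

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ResourceSchedule)
            and self.kinds == other.kinds
            and self.periods == other.periods
            and np.array_equal(self.n, other.n)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.n, index=list(self.kinds), columns=list(self.periods))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResourceSchedule":
        return cls(
            kinds=tuple(frame.index),
            periods=tuple(frame.columns),
            n=frame.to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="resource")

    @classmethod
    def from_csv(cls, path) -> "ResourceSchedule":
        return cls.from_frame(pd.read_csv(path, index_col="resource"))


@dataclass(eq=False)
class CostModel:
    """Per-period cost (Baht) of staffing one resource of each kind."""

    kinds: tuple[str, ...]
    periods: tuple[str, ...]
    c: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.kinds = tuple(self.kinds)
        self.periods = tuple(self.periods)
        c = np.asarray(self.c, dtype=float)
        if c.shape != (len(self.kinds), len(self.periods)):
            raise ValueError("cost matrix shape does not match kinds x periods")
        if (c < 0).any():
            raise ValueError("cost coefficients must be nonnegative")
        self.c = c

    @classmethod
    def unit(cls, kinds: tuple[str, ...],
             periods: tuple[str, ...] = ("07-09", "09-11", "11-13", "13-15"),
             cost: float = 1.0) -> "CostModel":
        """Flat cost per staffed resource per period (bundled test default —
        the department's true per-kind salary coefficients are private)."""
        return cls(kinds=tuple(kinds), periods=tuple(periods),
                   c=np.full((len(kinds), len(periods)), float(cost)))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CostModel)
            and self.kinds == other.kinds
            and self.periods == other.periods
            and np.array_equal(self.c, other.c)
        )
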