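"""Minimal discrete-event simulation kernel.

State changes only at event instants.  The kernel provides an event calendar
ordered by (time, insertion sequence), a simulation clock, and capacity-
scheduled resource pools with FIFO waiting queues.  Higher-level patient-flow
logic lives in :mod:`hospflow.flow`; this module knows nothing about patients
beyond opaque payloads.

Time is measured in minutes since the queue-ticket machine opens at 05:00.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Hashable, Iterable

__all__ = [
    "SimulationEnded",
    "StuckSystemError",
    "SimClock",
    "SimEvent",
    "EventCalendar",
    "ResourcePool",
    "ReplicationRecord",
    "run_replication",
    "HARD_CAP_MINUTES",
]

#: Diagnostic hard cap: a terminating one-day model that has not emptied by
#: this simulated time is declared stuck (e.g. a required station with zero
#: capacity all day).
HARD_CAP_MINUTES = 2000.0


class SimulationEnded(Exception):
    """Raised when the event calendar is popped empty."""


class StuckSystemError(RuntimeError):
    """The system cannot empty (entities stuck in queues past the hard cap)."""


@dataclass
class SimClock:
    """Simulation clock: minutes since 05:00, nondecreasing within a run."""

    now: float = 0.0
    replication_index: int = 0

    def advance(self, t: float) -> None:
        if t < self.now:
            raise ValueError(f"clock cannot move backwards: {t} < {self.now}")
        self.now = t


@dataclass(frozen=True)
class SimEvent:
    time: float
    seq: int
    kind: str
    payload: Any = None

    def sort_key(self) -> tuple[float, int]:
        return (self.time, self.seq)


class EventCalendar:
    """Future-event list keyed by (time, insertion order).

    Simultaneous events are dispatched in insertion order — a stable,
    reproducible tie-break.
    """

    def __init__(self, clock: SimClock) -> None:
        self._clock = clock
        self._heap: list[tuple[float, int, SimEvent]] = []
        self._seq = 0

    def __len__(self) -> int:
        return len(self._heap)

    def push(self, time: float, kind: str, payload: Any = None) -> SimEvent:
        """Schedule an event; scheduling in the past is a model bug."""
        if time < self._clock.now:
            raise ValueError(
                f"event {kind!r} scheduled at t={time} before clock t={self._clock.now}"
            )
        event = SimEvent(time=time, seq=self._seq, kind=kind, payload=payload)
        self._seq += 1
        heapq.heappush(self._heap, (time, event.seq, event))
        return event

    def pop(self) -> SimEvent:
        """Remove and return the minimum-(time, seq) event; advance the clock."""
        if not self._heap:
            raise SimulationEnded("event calendar is empty")
        _, _, event = heapq.heappop(self._heap)
        self._clock.advance(event.time)
        return event


class ResourcePool:
    """A bank of interchangeable servers with a period-varying capacity.

    Capacity changes are non-preemptive: when capacity drops at a period
    boundary, in-service entities finish and the excess busy servers drain
    naturally; no new service starts while ``busy >= capacity``.
    """

    def __init__(
        self,
        pool_id: Hashable,
        capacity_schedule: Iterable[tuple[float, int]],
    ) -> None:
        """``capacity_schedule`` is a sequence of (start_minute, capacity)
        breakpoints sorted by start; the first breakpoint must start at or
        before 0 and each capacity holds until the next breakpoint (the last
        one holds forever — counters serve until the queue empties)."""
        sched = sorted(capacity_schedule, key=lambda p: p[0])
        if not sched:
            raise ValueError("capacity schedule is empty")
        if sched[0][0] > 0:
            raise ValueError("capacity schedule must cover t=0")
        for _, cap in sched:
            if cap < 0 or int(cap) != cap:
                raise ValueError("capacities must be nonnegative integers")
        self.pool_id = pool_id
        self._schedule = [(float(t), int(c)) for t, c in sched]
        self.busy = 0
        self.cumulative_busy_time = 0.0
        self.wait_queue: deque[Any] = deque()

    def capacity_at(self, t: float) -> int:
        cap = self._schedule[0][1]
        for start, c in self._schedule:
            if start <= t:
                cap = c
            else:
                break
        return cap

    def idle_servers(self, t: float) -> int:
        return max(0, self.capacity_at(t) - self.busy)

    def utilization(self, t: float) -> float:
        """Cumulative finished busy time over elapsed open time (minutes)."""
        if t <= 0.0:
            return 0.0
        return self.cumulative_busy_time / t

    def seize(self, patient: Any, t: float) -> str:
        """Request a server: returns ``"in_service"`` (busy incremented) or
        ``"queued"`` (patient appended to the FIFO queue)."""
        if self.busy < self.capacity_at(t):
            self.busy += 1
            return "in_service"
        self.wait_queue.append(patient)
        return "queued"

    def release(self, t: float, service_duration: float) -> Any | None:
        """Finish one service.  Accrues the finished duration, decrements
        ``busy`` and, if capacity allows, starts the head of the queue —
        returned to the caller so it can schedule the service end."""
        if self.busy < 1:
            raise RuntimeError(f"release without seize on pool {self.pool_id!r}")
        self.busy -= 1
        self.cumulative_busy_time += service_duration
        return self._start_next(t)

    def _start_next(self, t: float) -> Any | None:
        if self.wait_queue and self.busy < self.capacity_at(t):
            self.busy += 1
            return self.wait_queue.popleft()
        return None

    def start_waiting(self, t: float) -> list[Any]:
        """Start as many queued entities as current capacity allows (used at
        period boundaries when capacity increases)."""
        started = []
        while True:
            nxt = self._start_next(t)
            if nxt is None:
                break
            started.append(nxt)
        return started


@dataclass
class ReplicationRecord:
    """Outcome of one simulated working day."""

    patients: list = field(default_factory=list)
    entered: int = 0
    left: int = 0
    end_time: float = 0.0

    def conservation_ok(self) -> bool:
        return self.entered == self.left == len(self.patients)


def run_replication(config, seed: int, deterministic: bool = False) -> ReplicationRecord:
    """Run one replication of the configured front-end model.

    Thin delegation to :func:`hospflow.flow.simulate_day`, which builds the
    hospital model on top of this kernel.
    """
    from .flow import simulate_day

    return simulate_day(config, seed, deterministic=deterministic)
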