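"""Hospital front-end patient-flow model.

Outpatients take a queue ticket (machine opens 05:00, closes 14:50), then
follow one of two paths:

* types 1-2: blood-pressure check -> nurse triage -> (fill-in form, new
  patients only) -> medical-record (MR) counter -> leave to the outpatient
  department;
* types 3-4: MR counter only.

Interarrival times are piecewise (shifted) exponential over three daily
segments; the patient-type mix varies over five two-hour windows; station
service times follow constant / shifted-exponential / shifted-Weibull /
triangular laws, in seconds.

Three MR routing policies are modeled:

* ``dedicated`` — each patient type has its own counter bank (current
  practice);
* ``one_stop``  — a single pooled counter bank serves every type;
* ``partial_shared`` — own-type counters first; when they are all busy the
  patient overflows to the eligible counter kind with the lowest utilization,
  and queues at its own-type bank only when nothing is idle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn

from .des import (
    HARD_CAP_MINUTES,
    EventCalendar,
    ReplicationRecord,
    ResourcePool,
    SimClock,
    SimulationEnded,
    StuckSystemError,
)
from .rng import substream
from .satisfaction import ScoreMapping, los_to_score, triangular_inverse_cdf
from .staffing import ResourceSchedule

__all__ = [
    "PATIENT_TYPES",
    "TICKET_CLOSE_MIN",
    "ArrivalSegment",
    "TypeMixWindow",
    "ServiceSpec",
    "Patient",
    "SCENARIO_POLICIES",
    "sample_interarrival",
    "assign_patient_type",
    "mean_service",
    "sample_service",
    "flow_path",
    "route_mrd",
    "simulate_day",
    "generate_arrival_times",
    "write_event_log",
]

PATIENT_TYPES: tuple[int, ...] = (1, 2, 3, 4)
#: Queue-ticket machine closes at 14:50 = 590 minutes after the 05:00 opening.
TICKET_CLOSE_MIN: float = 590.0
SCENARIO_POLICIES: tuple[str, ...] = ("dedicated", "one_stop", "partial_shared")

#: Stations modeled as pure delays (no staffed servers, hence no queue).
DELAY_STATIONS = frozenset({"blood_pressure", "fill_info"})


@dataclass(frozen=True)
class ArrivalSegment:
    """One interarrival regime: gap = shift + Exp(expo_mean), minutes."""

    start: float
    end: float
    shift: float
    expo_mean: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("arrival segment needs start < end")
        if self.expo_mean <= 0:
            raise ValueError("exponential mean must be positive")
        if self.shift < 0:
            raise ValueError("interarrival shift must be nonnegative")


@dataclass(frozen=True)
class TypeMixWindow:
    """Patient-type probabilities over a clock window."""

    start: float
    end: float
    probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("type-mix window needs start < end")
        if len(self.probs) != len(PATIENT_TYPES):
            raise ValueError("type mix needs one probability per patient type")
        if any(p < 0 for p in self.probs):
            raise ValueError("type-mix probabilities must be nonnegative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(
                f"type-mix probabilities must sum to 1 (got {sum(self.probs)})"
            )


_FAMILY_PARAMS = {
    "constant": ("value",),
    "shifted_exponential": ("shift", "mean"),
    "shifted_weibull": ("shift", "scale", "shape"),
    "triangular": ("min", "mode", "max"),
}


@dataclass(frozen=True)
class ServiceSpec:
    """Service-time law at one station, parameters in seconds."""

    station: str
    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown service family {self.family!r}")
        names = _FAMILY_PARAMS[self.family]
        if len(self.params) != len(names):
            raise ValueError(
                f"{self.family} expects parameters {names}, got {self.params}"
            )
        object.__setattr__(self, "params", tuple(float(v) for v in self.params))
        if self.family == "triangular":
            a, m, b = self.params
            if not a <= m <= b:
                raise ValueError("triangular needs min <= mode <= max")
            if a <= 0:
                raise ValueError("triangular support must be positive")
        elif any(v < 0 for v in self.params):
            raise ValueError("service parameters must be nonnegative")
        if self.family == "shifted_weibull" and (
            self.params[1] <= 0 or self.params[2] <= 0
        ):
            raise ValueError("Weibull scale and shape must be positive")
        if self.family == "shifted_exponential" and self.params[1] <= 0:
            raise ValueError("exponential mean must be positive")


def mean_service(spec: ServiceSpec) -> float:
    """Closed-form mean service time, seconds."""
    p = spec.params
    if spec.family == "constant":
        return p[0]
    if spec.family == "shifted_exponential":
        return p[0] + p[1]
    if spec.family == "shifted_weibull":
        shift, scale, shape = p
        return shift + scale * float(_gamma_fn(1.0 + 1.0 / shape))
    a, m, b = p  # triangular
    return (a + m + b) / 3.0


def sample_service(
    spec: ServiceSpec, rng: np.random.Generator, deterministic: bool = False
) -> float:
    """One service-time draw in seconds (the mean, in deterministic mode).

    Triangular draws use the inverse CDF so a given stream position maps to
    exactly one value; shifted draws always exceed their shift.
    """
    if deterministic:
        return mean_service(spec)
    p = spec.params
    if spec.family == "constant":
        return p[0]
    if spec.family == "shifted_exponential":
        return p[0] + rng.exponential(p[1])
    if spec.family == "shifted_weibull":
        shift, scale, shape = p
        return shift + scale * rng.weibull(shape)
    a, m, b = p
    return triangular_inverse_cdf(a, m, b, rng.random())


@dataclass
class Patient:
    """One simulated outpatient and its per-station timestamps (minutes)."""

    id: int
    ptype: int
    is_new: bool
    ticket_time: float
    station_times: dict[str, dict[str, float]] = field(default_factory=dict)
    los: float | None = None
    score: float | None = None
    pending: list[str] = field(default_factory=list, repr=False)

    @property
    def disposal_time(self) -> float | None:
        return None if self.los is None else self.ticket_time + self.los


def sample_interarrival(segment: ArrivalSegment, rng: np.random.Generator) -> float:
    """Draw one interarrival gap (minutes) under a segment's law."""
    return segment.shift + rng.exponential(segment.expo_mean)


def _segment_at(segments: Sequence[ArrivalSegment], t: float) -> ArrivalSegment:
    for seg in segments:
        if seg.start <= t < seg.end:
            return seg
    if t >= segments[-1].end:
        return segments[-1]
    raise ValueError(f"no arrival segment covers t={t}")


def generate_arrival_times(
    segments: Sequence[ArrivalSegment],
    close: float,
    rng: np.random.Generator,
) -> list[float]:
    """Ticket times for one day: cumulative interarrival gaps from opening,
    truncated at ticket close.  Each gap is drawn under the law of the segment
    containing the previous arrival instant; a gap crossing a segment boundary
    is kept as drawn."""
    times: list[float] = []
    t = 0.0
    while True:
        t = t + sample_interarrival(_segment_at(segments, t), rng)
        if t > close:
            return times
        times.append(t)


def assign_patient_type(
    windows: Sequence[TypeMixWindow], ticket_time: float, rng: np.random.Generator
) -> int:
    """Draw a patient type from the mix window containing the ticket time."""
    for w in windows:
        if w.start <= ticket_time < w.end:
            u = rng.random()
            cum = 0.0
            for ptype, p in zip(PATIENT_TYPES, w.probs):
                cum += p
                if u < cum:
                    return ptype
            return PATIENT_TYPES[-1]  # guard against float round-off
    raise ValueError(f"ticket time {ticket_time} outside every type-mix window")


def flow_path(ptype: int, is_new: bool) -> list[str]:
    """Ordered station list for a patient type / registration status."""
    if ptype in (1, 2):
        path = ["blood_pressure", "triage"]
        if is_new:
            path.append("fill_info")
        path.append("mr")
        return path
    if ptype in (3, 4):
        return ["mr"]
    raise ValueError(f"unknown patient type {ptype}")


def _service_key(station: str, ptype: int) -> str:
    # MR handling time depends on the patient's type, not on which counter
    # bank serves them.
    return f"mr_type{ptype}" if station == "mr" else station


#: Counter kinds a patient type may overflow to under partial sharing, in
#: tie-break (lowest-index) order.  M12 serves only types 1-2.
_MR_POOL_ORDER = ("M1", "M12", "M2", "M3", "M4")


def _eligible(kind: str, ptype: int) -> bool:
    if kind == "M12":
        return ptype in (1, 2)
    return True


def route_mrd(
    policy: str,
    patient: Patient,
    pools: Mapping[str, ResourcePool],
    clock: SimClock,
) -> ResourcePool:
    """Select the MR counter bank a patient contacts on entering the MRD.

    dedicated        -> the bank matching the patient's type, always.
    one_stop         -> the single pooled bank.
    partial_shared   -> own-type bank if a server is idle; otherwise the
                        eligible other bank with the lowest utilization that
                        has an idle server; otherwise queue at the own-type
                        bank.  Routing happens at entry only (no jockeying).
    """
    if policy == "one_stop":
        return pools["M"]
    own_kind = f"M{patient.ptype}"
    if own_kind not in pools:
        raise KeyError(
            f"no MR counter bank configured for patient type {patient.ptype} "
            f"under policy {policy!r}"
        )
    own = pools[own_kind]
    if policy == "dedicated":
        return own
    if policy != "partial_shared":
        raise ValueError(f"unknown MRD policy {policy!r}")
    now = clock.now
    if own.idle_servers(now) > 0:
        return own
    candidates = [
        pools[kind]
        for kind in _MR_POOL_ORDER
        if kind != own_kind
        and kind in pools
        and _eligible(kind, patient.ptype)
        and pools[kind].idle_servers(now) > 0
    ]
    if not candidates:
        return own
    return min(candidates, key=lambda p: (p.utilization(now), _MR_POOL_ORDER.index(p.pool_id)))


def _build_pools(policy: str, schedule: ResourceSchedule) -> tuple[dict, dict]:
    """Triage pools keyed N / N2 and MR pools keyed by counter kind."""
    def pool(kind: str) -> ResourcePool:
        return ResourcePool(kind, schedule.capacity_breakpoints(kind))

    triage = {"N": pool("N"), "N2": pool("N2")}
    if policy == "one_stop":
        mr = {"M": pool("M")}
    else:
        mr = {k: pool(k) for k in ("M1", "M2", "M3", "M4")}
        if "M12" in schedule.kinds and schedule.n[schedule.kinds.index("M12")].any():
            mr["M12"] = pool("M12")
    return triage, mr


class _DayEngine:
    """Event-driven execution of one working day."""

    def __init__(self, config, seed: int, deterministic: bool) -> None:
        self.config = config
        self.deterministic = deterministic
        self.clock = SimClock()
        self.calendar = EventCalendar(self.clock)
        self.policy = config.policy
        self.triage_pools, self.mr_pools = _build_pools(config.policy, config.schedule)
        self.services: dict[str, ServiceSpec] = dict(config.services)
        self.rng_service = {
            key: substream(seed, f"service:{key}") for key in self.services
        }
        self.rng_arrivals = substream(seed, "arrivals")
        self.rng_mix = substream(seed, "type_mix")
        self.rng_new = substream(seed, "new_flag")
        profiles = getattr(config, "profiles", None) or {}
        self.mappings = {
            t: ScoreMapping.from_profile(p) for t, p in profiles.items()
        }
        self.record = ReplicationRecord()

    # -- arrivals ----------------------------------------------------------

    def _arrivals(self) -> list[tuple[float, int, bool]]:
        forced = getattr(self.config, "forced_arrivals", None)
        if forced is not None:
            return [(float(t), int(p), bool(n)) for t, p, n in forced]
        close = getattr(self.config, "ticket_close", TICKET_CLOSE_MIN)
        times = generate_arrival_times(
            self.config.arrival_segments, close, self.rng_arrivals
        )
        out = []
        for t in times:
            ptype = assign_patient_type(self.config.mix_windows, t, self.rng_mix)
            is_new = ptype in (1, 2) and self.rng_new.random() < self.config.p_new
            out.append((t, ptype, is_new))
        return out

    # -- stage machinery ---------------------------------------------------

    def _sample_minutes(self, station: str, ptype: int) -> float:
        key = _service_key(station, ptype)
        spec = self.services[key]
        return sample_service(spec, self.rng_service[key], self.deterministic) / 60.0

    def _times(self, patient: Patient, station: str) -> dict[str, float]:
        return patient.station_times.setdefault(station, {})

    def _begin_stage(self, patient: Patient) -> None:
        if not patient.pending:
            self._dispose(patient)
            return
        station = patient.pending[0]
        now = self.clock.now
        if station in DELAY_STATIONS:
            t = self._times(patient, station)
            t["arrive"] = t["start"] = now
            dur = self._sample_minutes(station, patient.ptype)
            self.calendar.push(now + dur, "service_end", (patient, station, None, dur))
            return
        pool = self._pool_for(patient, station)
        self._times(patient, station)["arrive"] = now
        if pool.seize(patient, now) == "in_service":
            self._start_service(patient, pool)

    def _pool_for(self, patient: Patient, station: str) -> ResourcePool:
        if station == "triage":
            return self.triage_pools["N" if patient.ptype == 1 else "N2"]
        if station == "mr":
            return route_mrd(self.policy, patient, self.mr_pools, self.clock)
        raise ValueError(f"station {station!r} has no resource pool")

    def _start_service(self, patient: Patient, pool: ResourcePool) -> None:
        station = patient.pending[0]
        now = self.clock.now
        self._times(patient, station)["start"] = now
        dur = self._sample_minutes(station, patient.ptype)
        self.calendar.push(now + dur, "service_end", (patient, station, pool, dur))

    def _end_stage(self, patient: Patient, station: str, pool, dur: float) -> None:
        now = self.clock.now
        self._times(patient, station)["depart"] = now
        patient.pending.pop(0)
        if pool is not None:
            nxt = pool.release(now, dur)
            if nxt is not None:
                self._start_service(nxt, pool)
        self._begin_stage(patient)

    def _dispose(self, patient: Patient) -> None:
        patient.los = self.clock.now - patient.ticket_time
        mapping = self.mappings.get(patient.ptype)
        if mapping is not None:
            patient.score = los_to_score(mapping, patient.los)
        self.record.left += 1
        self.record.patients.append(patient)

    # -- run ---------------------------------------------------------------

    def run(self) -> ReplicationRecord:
        arrivals = self._arrivals()
        for i, (t, ptype, is_new) in enumerate(arrivals):
            patient = Patient(
                id=i + 1,
                ptype=ptype,
                is_new=is_new,
                ticket_time=t,
                pending=flow_path(ptype, is_new),
            )
            self.calendar.push(t, "arrival", patient)
        all_pools = list(self.triage_pools.values()) + list(self.mr_pools.values())
        boundaries = sorted(
            {start for pool in all_pools for start, _ in pool._schedule if start > 0}
        )
        for b in boundaries:
            self.calendar.push(b, "period_change", None)
        self.calendar.push(600.0, "terminate_check", None)

        last_time = 0.0
        while True:
            try:
                event = self.calendar.pop()
            except SimulationEnded:
                break
            if self.clock.now > HARD_CAP_MINUTES:
                raise StuckSystemError(
                    f"system has not emptied by t={self.clock.now:.0f} min "
                    f"(hard cap {HARD_CAP_MINUTES:.0f})"
                )
            last_time = event.time
            if event.kind == "arrival":
                self.record.entered += 1
                self._begin_stage(event.payload)
            elif event.kind == "service_end":
                self._end_stage(*event.payload)
            elif event.kind == "period_change":
                for pool in all_pools:
                    for patient in pool.start_waiting(self.clock.now):
                        self._start_service(patient, pool)
            elif event.kind == "terminate_check":
                pass  # the terminating rule itself is entered == left below

        self.record.end_time = max(600.0, last_time)
        if self.record.entered != self.record.left:
            stuck = {
                pool.pool_id: len(pool.wait_queue)
                for pool in all_pools
                if pool.wait_queue
            }
            raise StuckSystemError(
                f"{self.record.entered - self.record.left} entities never left "
                f"the system; waiting per pool: {stuck}"
            )
        return self.record


def simulate_day(config, seed: int, deterministic: bool = False) -> ReplicationRecord:
    """Run one replication (one working day) of the configured model.

    Arrivals are generated from the 05:00 opening until ticket close; the run
    continues past the 600-minute mark until every patient who entered has
    left (no warm-up truncation — the whole day counts).  Identical
    (config, seed) pairs produce identical event traces.
    """
    return _DayEngine(config, seed, deterministic).run()


_LOG_STATIONS = ("blood_pressure", "triage", "fill_info", "mr")


def event_log_frame(patients: Iterable[Patient]) -> pd.DataFrame:
    """Per-patient event log: one row per patient, per-station timestamps."""
    rows = []
    for p in patients:
        row: dict = {
            "id": p.id,
            "type": p.ptype,
            "is_new": p.is_new,
            "ticket_time": p.ticket_time,
        }
        for st in _LOG_STATIONS:
            times = p.station_times.get(st, {})
            for what in ("arrive", "start", "depart"):
                row[f"{st}_{what}"] = times.get(what, math.nan)
        row["los"] = p.los
        row["score"] = p.score
        rows.append(row)
    return pd.DataFrame(rows)


def write_event_log(patients: Iterable[Patient], path) -> None:
    event_log_frame(patients).to_csv(path, index=False)
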