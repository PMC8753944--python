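"""Model configuration: validated loading with case-study defaults.

A model configuration bundles everything a simulated day needs: arrival
segments, the patient-type mix, station service laws, satisfaction profiles,
the MRD routing policy, the staffing schedule, and cost coefficients.
Configurations are plain YAML (JSON is valid YAML) with clock times written
"HH:MM"; internally all times are minutes since the 05:00 opening.  Any
section missing from a file is filled from the bundled defaults, which
reproduce the case-study inputs verbatim.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .flow import (
    PATIENT_TYPES,
    TICKET_CLOSE_MIN,
    ArrivalSegment,
    ServiceSpec,
    TypeMixWindow,
)
from .satisfaction import DEFAULT_PROFILES, SatisfactionProfile, TriangularSpec
from .staffing import CostModel, ResourceSchedule

__all__ = [
    "ConfigError",
    "ModelConfig",
    "RunManifest",
    "parse_clock",
    "format_clock",
    "default_arrival_segments",
    "default_mix_windows",
    "default_services",
    "default_schedule",
    "default_config",
    "load_config",
    "dump_config",
]

#: The day's origin: the queue-ticket machine opens at 05:00.
OPENING_CLOCK = "05:00"
_OPENING_MINUTES = 5 * 60


class ConfigError(ValueError):
    """A configuration file violated the model's invariants."""


def parse_clock(text: str) -> float:
    """'HH:MM' wall-clock -> minutes since the 05:00 opening."""
    try:
        h, m = text.strip().split(":")
        minutes = int(h) * 60 + int(m) - _OPENING_MINUTES
    except (ValueError, AttributeError) as exc:
        raise ConfigError(f"bad clock time {text!r}; expected 'HH:MM'") from exc
    if minutes < 0:
        raise ConfigError(f"clock time {text!r} precedes the 05:00 opening")
    return float(minutes)


def format_clock(minutes: float) -> str:
    total = int(round(minutes)) + _OPENING_MINUTES
    return f"{total // 60:02d}:{total % 60:02d}"


# ---------------------------------------------------------------------------
# defaults (the case-study inputs)


def default_arrival_segments() -> list[ArrivalSegment]:
    """Piecewise interarrival law: a quiet opening hour, a morning peak with a
    0.5-min floor, and a slower afternoon tail."""
    return [
        ArrivalSegment(start=parse_clock("05:00"), end=parse_clock("06:00"),
                       shift=0.0, expo_mean=10.0),
        ArrivalSegment(start=parse_clock("06:00"), end=parse_clock("10:30"),
                       shift=0.5, expo_mean=1.24),
        ArrivalSegment(start=parse_clock("10:30"), end=parse_clock("15:00"),
                       shift=0.0, expo_mean=2.67),
    ]


def default_mix_windows() -> list[TypeMixWindow]:
    """Patient-type probabilities over five two-hour windows."""
    raw = [
        ("05:00", "07:00", (0.36, 0.10, 0.08, 0.46)),
        ("07:00", "09:00", (0.35, 0.10, 0.11, 0.44)),
        ("09:00", "11:00", (0.27, 0.09, 0.10, 0.54)),
        ("11:00", "13:00", (0.26, 0.10, 0.10, 0.54)),
        ("13:00", "15:00", (0.26, 0.10, 0.10, 0.54)),
    ]
    return [
        TypeMixWindow(start=parse_clock(s), end=parse_clock(e), probs=p)
        for s, e, p in raw
    ]


def default_services() -> dict[str, ServiceSpec]:
    """Station service laws (seconds)."""
    return {
        "blood_pressure": ServiceSpec("blood_pressure", "constant", (49.0,)),
        "triage": ServiceSpec("triage", "shifted_exponential", (25.0, 71.2)),
        "fill_info": ServiceSpec("fill_info", "constant", (300.0,)),
        "mr_type1": ServiceSpec("mr_type1", "shifted_weibull", (14.0, 47.4, 0.94)),
        "mr_type2": ServiceSpec("mr_type2", "shifted_weibull", (14.0, 47.4, 0.94)),
        "mr_type3": ServiceSpec("mr_type3", "triangular", (84.0, 146.8, 251.0)),
        "mr_type4": ServiceSpec("mr_type4", "triangular", (59.0, 72.8, 197.0)),
    }


#: The one staffing row published for the case study (the 07:00-09:00 levels
#: of the best-satisfaction solution), used as the example/default schedule
#: in every period.
_DEFAULT_LEVELS = {"N": 6, "N2": 3, "M1": 3, "M2": 3, "M3": 2, "M4": 10}


def default_schedule(policy: str = "dedicated") -> ResourceSchedule:
    if policy == "one_stop":
        mr_total = sum(v for k, v in _DEFAULT_LEVELS.items() if k.startswith("M"))
        levels = {"N": _DEFAULT_LEVELS["N"], "N2": _DEFAULT_LEVELS["N2"], "M": mr_total}
    else:
        levels = dict(_DEFAULT_LEVELS)
    return ResourceSchedule.uniform(levels)


@dataclass
class ModelConfig:
    """Everything one simulated day needs."""

    arrival_segments: list[ArrivalSegment]
    mix_windows: list[TypeMixWindow]
    services: dict[str, ServiceSpec]
    profiles: dict[int, SatisfactionProfile]
    schedule: ResourceSchedule
    policy: str = "dedicated"
    p_new: float = 0.0
    ticket_close: float = TICKET_CLOSE_MIN
    cost_model: CostModel | None = None
    forced_arrivals: list[tuple[float, int, bool]] | None = None

    def __post_init__(self) -> None:
        if self.policy not in ("dedicated", "one_stop", "partial_shared"):
            raise ConfigError(f"unknown policy {self.policy!r}")
        if not 0.0 <= self.p_new <= 1.0:
            raise ConfigError("p_new must be a probability")
        required = {"blood_pressure", "triage", "fill_info"} | {
            f"mr_type{t}" for t in PATIENT_TYPES
        }
        missing = required - set(self.services)
        if missing:
            raise ConfigError(f"missing service specs: {sorted(missing)}")
        if set(self.profiles) != set(PATIENT_TYPES):
            raise ConfigError("need one satisfaction profile per patient type")
        needed_kinds = (
            {"N", "N2", "M"}
            if self.policy == "one_stop"
            else {"N", "N2", "M1", "M2", "M3", "M4"}
        )
        missing_kinds = needed_kinds - set(self.schedule.kinds)
        if missing_kinds:
            raise ConfigError(
                f"schedule lacks resource kinds {sorted(missing_kinds)} "
                f"required by policy {self.policy!r}"
            )


def default_config(policy: str = "dedicated", p_new: float = 0.0) -> ModelConfig:
    """The full bundled default configuration."""
    return ModelConfig(
        arrival_segments=default_arrival_segments(),
        mix_windows=default_mix_windows(),
        services=default_services(),
        profiles=dict(DEFAULT_PROFILES),
        schedule=default_schedule(policy),
        policy=policy,
        p_new=p_new,
    )


# ---------------------------------------------------------------------------
# (de)serialization


_FAMILY_FIELDS = {
    "constant": ("value_s",),
    "shifted_exponential": ("shift_s", "mean_s"),
    "shifted_weibull": ("shift_s", "scale_s", "shape"),
    "triangular": ("min_s", "mode_s", "max_s"),
}


def _service_to_dict(spec: ServiceSpec) -> dict:
    out = {"family": spec.family}
    out.update(zip(_FAMILY_FIELDS[spec.family], spec.params))
    return out


def _service_from_dict(station: str, data: dict) -> ServiceSpec:
    family = data.get("family")
    if family not in _FAMILY_FIELDS:
        raise ConfigError(f"service {station!r}: unknown family {family!r}")
    try:
        params = tuple(float(data[k]) for k in _FAMILY_FIELDS[family])
    except KeyError as exc:
        raise ConfigError(
            f"service {station!r}: family {family!r} needs fields "
            f"{_FAMILY_FIELDS[family]}"
        ) from exc
    try:
        return ServiceSpec(station, family, params)
    except ValueError as exc:
        raise ConfigError(f"service {station!r}: {exc}") from exc


def config_to_dict(config: ModelConfig) -> dict:
    return {
        "policy": config.policy,
        "p_new": config.p_new,
        "ticket_close": format_clock(config.ticket_close),
        "arrivals": [
            {
                "start": format_clock(s.start),
                "end": format_clock(s.end),
                "shift_min": s.shift,
                "expo_mean_min": s.expo_mean,
            }
            for s in config.arrival_segments
        ],
        "type_mix": [
            {
                "start": format_clock(w.start),
                "end": format_clock(w.end),
                "probs": list(w.probs),
            }
            for w in config.mix_windows
        ],
        "services": {
            name: _service_to_dict(spec) for name, spec in config.services.items()
        },
        "satisfaction": {
            str(t): {
                "los_min": [p.los_tri.optimistic, p.los_tri.most_likely,
                            p.los_tri.pessimistic],
                "score_pct": [p.score_tri.optimistic, p.score_tri.most_likely,
                              p.score_tri.pessimistic],
            }
            for t, p in config.profiles.items()
        },
        "schedule": {
            "periods": list(config.schedule.periods),
            "rows": {
                k: config.schedule.n[i].tolist()
                for i, k in enumerate(config.schedule.kinds)
            },
        },
    }


def _build_config(data: dict) -> ModelConfig:
    policy = data.get("policy", "dedicated")

    if "arrivals" in data:
        try:
            segments = [
                ArrivalSegment(
                    start=parse_clock(seg["start"]),
                    end=parse_clock(seg["end"]),
                    shift=float(seg.get("shift_min", 0.0)),
                    expo_mean=float(seg["expo_mean_min"]),
                )
                for seg in data["arrivals"]
            ]
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"bad arrivals section: {exc}") from exc
    else:
        segments = default_arrival_segments()

    if "type_mix" in data:
        try:
            windows = [
                TypeMixWindow(
                    start=parse_clock(w["start"]),
                    end=parse_clock(w["end"]),
                    probs=tuple(float(p) for p in w["probs"]),
                )
                for w in data["type_mix"]
            ]
        except ConfigError:
            raise
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"bad type_mix section: {exc}") from exc
    else:
        windows = default_mix_windows()

    services = default_services()
    for name, spec_data in (data.get("services") or {}).items():
        services[name] = _service_from_dict(name, spec_data)

    profiles = dict(DEFAULT_PROFILES)
    for key, pdata in (data.get("satisfaction") or {}).items():
        t = int(key)
        try:
            profiles[t] = SatisfactionProfile(
                ptype=t,
                los_tri=TriangularSpec(*[float(v) for v in pdata["los_min"]]),
                score_tri=TriangularSpec(*[float(v) for v in pdata["score_pct"]]),
            )
        except ValueError as exc:
            raise ConfigError(f"satisfaction profile {key!r}: {exc}") from exc

    if "schedule" in data:
        sched_data = data["schedule"]
        try:
            schedule = ResourceSchedule.from_rows(
                {k: list(v) for k, v in sched_data["rows"].items()},
                tuple(sched_data["periods"]),
            )
        except ValueError as exc:
            raise ConfigError(f"bad schedule section: {exc}") from exc
    else:
        schedule = default_schedule(policy)

    ticket_close = (
        parse_clock(data["ticket_close"])
        if "ticket_close" in data
        else TICKET_CLOSE_MIN
    )

    try:
        return ModelConfig(
            arrival_segments=segments,
            mix_windows=windows,
            services=services,
            profiles=profiles,
            schedule=schedule,
            policy=policy,
            p_new=float(data.get("p_new", 0.0)),
            ticket_close=ticket_close,
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration.

    Missing sections are filled from the bundled defaults; an empty file
    yields the full default configuration.  Violations of the model's
    invariants (probability rows not summing to one, non-monotone triangular
    parameters, negative staffing, ...) raise :class:`ConfigError` naming the
    offending section.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    try:
        return _build_config(data)
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: ModelConfig, path) -> None:
    """Write a configuration as YAML; loading it back yields an equal object."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# run manifests


@dataclass
class RunManifest:
    """Provenance record written next to every artifact a run produces."""

    command: str
    seed: int
    scenario: str
    replications: int = 1
    config_path: str | None = None
    schedule_path: str | None = None
    tool_version: str = "0.1.0"
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())
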