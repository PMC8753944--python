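"""Patient-flow model: sampling laws, paths, routing, day simulation."""

import dataclasses
import math

import numpy as np
import pytest

from hospflow.config import default_schedule
from hospflow.des import SimClock, StuckSystemError
from hospflow.flow import (
    TICKET_CLOSE_MIN,
    ArrivalSegment,
    Patient,
    ServiceSpec,
    TypeMixWindow,
    assign_patient_type,
    flow_path,
    generate_arrival_times,
    mean_service,
    route_mrd,
    sample_interarrival,
    sample_service,
    simulate_day,
)
from hospflow.des import ResourcePool
from hospflow.satisfaction import average_satisfaction
from hospflow.staffing import ResourceSchedule


class StubRng:
    """Fixed-draw stand-in for a numpy Generator."""

    def __init__(self, expo=0.0, uniform=0.0):
        self._expo = expo
        self._uniform = uniform

    def exponential(self, mean):
        return self._expo

    def random(self):
        return self._uniform


class TestInterarrival:
    def test_unshifted_segment_passes_draw_through(self):
        seg = ArrivalSegment(0.0, 60.0, shift=0.0, expo_mean=10.0)
        assert sample_interarrival(seg, StubRng(expo=10.0)) == 10.0

    def test_shift_added(self):
        seg = ArrivalSegment(60.0, 330.0, shift=0.5, expo_mean=1.24)
        assert sample_interarrival(seg, StubRng(expo=1.24)) == pytest.approx(1.74)

    def test_afternoon_mean_recovers(self, rng):
        seg = ArrivalSegment(330.0, 600.0, shift=0.0, expo_mean=2.67)
        draws = [sample_interarrival(seg, rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(2.67, abs=0.03)

    def test_arrivals_stop_at_ticket_close(self, base_config, rng):
        for _ in range(5):
            times = generate_arrival_times(
                base_config.arrival_segments, TICKET_CLOSE_MIN, rng
            )
            assert all(t <= TICKET_CLOSE_MIN for t in times)
            assert times == sorted(times)


class TestTypeAssignment:
    WINDOW = TypeMixWindow(240.0, 360.0, (0.27, 0.09, 0.10, 0.54))

    def test_last_share_maps_to_type_4(self):
        # cumulative .27/.36/.46; any draw beyond .46 is the 54% type-4 share
        assert assign_patient_type([self.WINDOW], 250.0, StubRng(uniform=0.47)) == 4
        assert assign_patient_type([self.WINDOW], 250.0, StubRng(uniform=0.999)) == 4

    def test_degenerate_mix(self):
        w = TypeMixWindow(0.0, 600.0, (1.0, 0.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        assert all(assign_patient_type([w], 1.0, rng) == 1 for _ in range(100))

    def test_outside_all_windows_errors(self):
        with pytest.raises(ValueError, match="outside"):
            assign_patient_type([self.WINDOW], 10.0, StubRng())

    def test_mix_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TypeMixWindow(0.0, 120.0, (0.5, 0.5, 0.5, 0.5))


class TestServiceLaws:
    def test_constant_mean(self, base_config):
        assert mean_service(base_config.services["blood_pressure"]) == 49.0

    def test_triangular_mean(self):
        spec = ServiceSpec("mr_type4", "triangular", (59.0, 72.8, 197.0))
        assert mean_service(spec) == pytest.approx(109.6, abs=1e-9)

    def test_shifted_weibull_mean_closed_form(self):
        spec = ServiceSpec("mr_type1", "shifted_weibull", (14.0, 47.4, 0.94))
        expected = 14.0 + 47.4 * math.gamma(1.0 + 1.0 / 0.94)
        assert mean_service(spec) == pytest.approx(expected)
        assert expected == pytest.approx(62.8, abs=0.1)

    def test_deterministic_draw_is_mean(self, base_config, rng):
        spec = base_config.services["triage"]
        assert sample_service(spec, rng, deterministic=True) == pytest.approx(96.2)

    def test_triangular_support(self, rng):
        spec = ServiceSpec("mr_type3", "triangular", (84.0, 146.8, 251.0))
        draws = [sample_service(spec, rng) for _ in range(10_000)]
        assert min(draws) >= 84.0 and max(draws) <= 251.0

    def test_shifted_draws_exceed_shift(self, base_config, rng):
        for key in ("triage", "mr_type1"):
            spec = base_config.services[key]
            shift = spec.params[0]
            assert all(
                sample_service(spec, rng) >= shift for _ in range(1000)
            )

    def test_weibull_sample_mean_matches_closed_form(self, base_config, rng):
        spec = base_config.services["mr_type1"]
        draws = np.array([sample_service(spec, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(mean_service(spec), abs=0.5)


class TestFlowPath:
    @pytest.mark.parametrize(
        "ptype,is_new,expected",
        [
            (1, False, ["blood_pressure", "triage", "mr"]),
            (1, True, ["blood_pressure", "triage", "fill_info", "mr"]),
            (2, False, ["blood_pressure", "triage", "mr"]),
            (3, False, ["mr"]),
            (4, False, ["mr"]),
        ],
    )
    def test_paths(self, ptype, is_new, expected):
        assert flow_path(ptype, is_new) == expected


def _pool(kind, cap, busy=0, busy_time=0.0):
    p = ResourcePool(kind, [(0.0, cap)])
    p.busy = busy
    p.cumulative_busy_time = busy_time
    return p


class TestRouting:
    def test_dedicated_own_type_always(self):
        pools = {f"M{t}": _pool(f"M{t}", 1) for t in (1, 2, 3, 4)}
        pools["M3"].busy = 1  # still routed there, even if busy
        patient = Patient(1, 3, False, 0.0)
        assert route_mrd("dedicated", patient, pools, SimClock()) is pools["M3"]

    def test_one_stop_single_bank(self):
        pools = {"M": _pool("M", 5)}
        for t in (1, 2, 3, 4):
            assert route_mrd("one_stop", Patient(1, t, False, 0.0), pools, SimClock()) is pools["M"]

    def test_partial_prefers_idle_own(self):
        pools = {f"M{t}": _pool(f"M{t}", 1) for t in (1, 2, 3, 4)}
        patient = Patient(1, 3, False, 0.0)
        assert route_mrd("partial_shared", patient, pools, SimClock()) is pools["M3"]

    def test_partial_overflows_to_least_utilized_idle(self):
        clock = SimClock(now=100.0)
        pools = {
            "M1": _pool("M1", 1, busy=0, busy_time=90.0),  # util 0.9
            "M2": _pool("M2", 1, busy=1, busy_time=10.0),  # busy, ineligible
            "M3": _pool("M3", 1, busy=1, busy_time=50.0),  # own, full
            "M4": _pool("M4", 1, busy=0, busy_time=20.0),  # util 0.2
        }
        patient = Patient(1, 3, False, 0.0)
        assert route_mrd("partial_shared", patient, pools, clock) is pools["M4"]

    def test_partial_queues_at_own_when_nothing_idle(self):
        pools = {f"M{t}": _pool(f"M{t}", 1, busy=1) for t in (1, 2, 3, 4)}
        patient = Patient(1, 2, False, 0.0)
        assert route_mrd("partial_shared", patient, pools, SimClock()) is pools["M2"]

    def test_m12_not_eligible_for_type_3(self):
        clock = SimClock(now=100.0)
        pools = {f"M{t}": _pool(f"M{t}", 1, busy=1) for t in (1, 2, 3, 4)}
        pools["M12"] = _pool("M12", 1, busy=0, busy_time=0.0)
        assert route_mrd("partial_shared", Patient(1, 3, False, 0.0), pools, clock) is pools["M3"]
        assert route_mrd("partial_shared", Patient(2, 2, False, 0.0), pools, clock) is pools["M12"]

    def test_dedicated_missing_pool_is_config_error(self):
        with pytest.raises(KeyError, match="no MR counter bank"):
            route_mrd("dedicated", Patient(1, 4, False, 0.0), {"M1": _pool("M1", 1)}, SimClock())


class TestSimulateDay:
    def test_single_type2_verification_los(self, base_config):
        cfg = dataclasses.replace(base_config, forced_arrivals=[(0.0, 2, False)])
        rec = simulate_day(cfg, seed=0, deterministic=True)
        assert rec.patients[0].los == pytest.approx(3.47, abs=0.005)

    def test_new_patient_adds_form_filling(self, base_config):
        cfg = dataclasses.replace(base_config, forced_arrivals=[(0.0, 1, True)])
        rec = simulate_day(cfg, seed=0, deterministic=True)
        assert rec.patients[0].los == pytest.approx(3.47 + 5.0, abs=0.005)

    def test_zero_triage_capacity_diagnosed(self, base_config):
        sched = ResourceSchedule.uniform(
            {"N": 0, "N2": 3, "M1": 3, "M2": 3, "M3": 2, "M4": 10}
        )
        cfg = dataclasses.replace(base_config, schedule=sched)
        with pytest.raises(StuckSystemError, match="never left"):
            simulate_day(cfg, seed=3)

    def test_determinism_of_satisfaction(self, base_config):
        a = simulate_day(base_config, seed=42)
        b = simulate_day(base_config, seed=42)
        assert average_satisfaction(a.patients) == average_satisfaction(b.patients)

    def test_no_ticket_after_close(self, base_config):
        rec = simulate_day(base_config, seed=5)
        assert max(p.ticket_time for p in rec.patients) <= 590.0

    @pytest.mark.parametrize("policy", ["one_stop", "partial_shared"])
    def test_alternative_policies_run_clean(self, base_config, policy):
        cfg = dataclasses.replace(
            base_config, policy=policy, schedule=default_schedule(policy)
        )
        rec = simulate_day(cfg, seed=9)
        assert rec.conservation_ok()
        assert all(p.score is not None for p in rec.patients)

    def test_partial_shared_no_idle_wait(self, base_config, tight_schedule):
        """A patient never queues at MRD while an eligible counter is idle."""
        cfg = dataclasses.replace(
            base_config, policy="partial_shared", schedule=tight_schedule
        )
        rec = simulate_day(cfg, seed=13)
        # With single-server banks and overflow allowed anywhere, a patient
        # waits only when every bank is simultaneously busy; so whenever one
        # waited, the four MR starts bracketing its arrival must all be busy.
        # Cheap proxy check: total waiting is below the dedicated run's.
        ded = simulate_day(dataclasses.replace(base_config, schedule=tight_schedule), seed=13)
        wait = lambda r: np.mean([
            p.station_times["mr"]["start"] - p.station_times["mr"]["arrive"]
            for p in r.patients
        ])
        assert wait(rec) <= wait(ded) + 1e-9
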