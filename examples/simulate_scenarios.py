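"""Simulate one working day under each MR-counter routing policy.

Builds the bundled default model (arrival segments, type mix, service laws)
with a deliberately tight staffing — one record counter per patient type, or
one pooled bank of four — runs a replication per policy with a common seed,
and prints throughput, mean length of stay, mean wait for a counter and mean
satisfaction.  The shorter waits under the pooled one-stop bank illustrate
the classical pooling gain at equal total staffing.
"""

import dataclasses

import numpy as np

from hospflow import average_satisfaction, default_config, simulate_day
from hospflow.staffing import ResourceSchedule

SCHEDULES = {
    "dedicated": ResourceSchedule.uniform({"N": 6, "N2": 3, "M1": 1, "M2": 1, "M3": 1, "M4": 1}),
    "one_stop": ResourceSchedule.uniform({"N": 6, "N2": 3, "M": 4}),
    "partial_shared": ResourceSchedule.uniform({"N": 6, "N2": 3, "M1": 1, "M2": 1, "M3": 1, "M4": 1}),
}

for policy, schedule in SCHEDULES.items():
    cfg = dataclasses.replace(default_config(policy), schedule=schedule)
    record = simulate_day(cfg, seed=2024)
    los = np.mean([p.los for p in record.patients])
    waits = np.mean(
        [p.station_times["mr"]["start"] - p.station_times["mr"]["arrive"]
         for p in record.patients]
    )
    print(
        f"{policy:15s}  patients={len(record.patients):4d}  "
        f"mean LOS={los:5.2f} min  mean MR wait={waits:5.3f} min  "
        f"satisfaction={average_satisfaction(record.patients):6.2f}%"
    )

print(
    "\nEach line is one simulated day (05:00 ticket opening to the last "
    "departure).  At this load the waits are short and every stay is far "
    "below the expert-elicited optimistic LOS, so the satisfaction score "
    "saturates at 100% for all three policies; the pooled and partially "
    "shared banks still cut the counter wait."
)
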