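# Methods

## The system being modeled

A public-hospital front-end department: every outpatient takes a queue
ticket (machine opens 05:00, closes 14:50), and is one of four types —
(1) walk-ins without an appointment, (2) university staff/students,
(3) patients with unregistered privileges or profile changes, (4) patients
with government coverage.  Types 1–2 pass a blood-pressure check, nurse
triage, a 300-second form for first-time registrants, and then a
medical-record (MR) counter; types 3–4 contact an MR counter directly.
The MR counters can be organized three ways (the *scenarios*): dedicated
banks per patient type, a single pooled one-stop bank, or dedicated banks
with overflow to the least-utilized other kind (partially shared).

## Simulation model

A terminating discrete-event simulation; one replication is one working
day.  State changes only at event instants; the event calendar orders
events by (time, insertion sequence), so simultaneous events dispatch in
insertion order and runs are exactly reproducible.

**Stochastic inputs** (defaults bundled in `config.py`):

| input | law | default |
|---|---|---|
| interarrival gaps | shifted exponential per segment | 05:00–06:00 Exp(10); 06:00–10:30 0.5+Exp(1.24); 10:30–15:00 Exp(2.67) (minutes) |
| patient type | categorical per 2-h window | e.g. 9–11 h: (27, 9, 10, 54) % |
| blood pressure | constant | 49 s |
| triage | shifted exponential | 25 + Exp(71.2) s |
| form filling | constant | 300 s |
| MR, types 1–2 | shifted Weibull | 14 + Weib(scale 47.4, shape 0.94) s |
| MR, type 3 | triangular | Tria(84, 146.8, 251) s |
| MR, type 4 | triangular | Tria(59, 72.8, 197) s |

Every source draws from its own named substream derived from the
replication seed (common random numbers across staffing candidates).
Triangular variates use the inverse CDF so one uniform draw maps to one
value.  An interarrival gap drawn in one segment that lands in the next is
kept as drawn (no rejection or rescaling) — the simplest consistent reading
of a piecewise specification.  The fraction of *new* patients `p_new`
defaults to 0: it is not published, and 0 reproduces the only exact
verification anchor (which excludes the 300-s form step); it is a config
field, not a constant.

**Termination.** Arrivals stop at ticket close (590 min after opening); the
day ends when every patient who entered has left, never before the 600-min
mark.  There is no warm-up truncation: the department starts empty each
day, and the whole day is the object of study.  A day that has not emptied
by 2000 simulated minutes — e.g. a required station given zero capacity all
day — raises a stuck-system diagnostic instead of looping forever; the same
diagnostic fires if the event calendar empties with patients still queued.

**Staffing and capacity changes.** Staffing is an integer matrix over
two-hour periods (05–07, 07–09, …, 13–15).  Four-period schedules are
extended back to the opening at the 07–09 level, and the last period's
level holds until the queues drain.  Capacity changes are non-preemptive:
when capacity drops at a boundary, in-service patients finish and the
excess drains naturally; no new service starts while `busy >= capacity`.

**Routing.** Queues are FIFO; routing happens once, at MRD entry (no
jockeying).  Under partial sharing a patient takes its own-type bank if a
server is idle; otherwise the eligible other bank with an idle server and
the lowest utilization (cumulative finished busy time over elapsed open
time, ties broken by bank order M1, M12, M2, M3, M4); otherwise it queues
at its own-type bank — so no patient ever waits while a bank it may use is
idle.  The M12 kind (counters serving types 1 and 2) is eligible only to
those types and only participates under partial sharing; the dedicated
router sends each type strictly to its own bank.  Blood pressure and form
filling are modeled as pure delays (no staffed servers are attached to them
in the staffing legend).

## Satisfaction scoring

Experts (the department chief and four senior nurses) gave, per patient
type, optimistic / most-likely / pessimistic LOS values and the scores
attached to them (100/75/50 % throughout): triangular elicitations.  The
score mapping standardizes a stay by the LOS triangular moments
(mean `(a+m+b)/3`, variance `(a²+m²+b²−am−ab−mb)/18`) and de-standardizes
on the score side, **imposing the negative direction** (longer stay, lower
score) and clamping to [0, 100].  The original study computed these means
and SDs from collected data that was never published; the triangular
moments are the only reproducible choice, and an `empirical` mapping
accepting user-supplied (mean, SD) pairs is provided for sites that have
their own data.

*Consequence (the score ceiling):* any stay shorter than roughly the
optimistic elicitation scores 100 %.  A well-staffed simulated day with
minute-scale waits therefore saturates at 100 % mean satisfaction — which
is why the bundled reference optima's satisfaction levels (≤ 90.6 %) are
**not** value-matched by this package: reproducing them would require the
original department's unpublished staffing baseline and congestion.  Tests
against those levels are replay checks on the printed numbers, not
re-simulations.

## Optimization

Cost is linear: `Z_cost = Σ_t Σ_i c_{i,t} n_{i,t}` (Baht/day).  Cost
coefficients are required configuration — the study printed only aggregate
daily costs, never `c_{i,t}` — and bundled examples use unit costs.  The
satisfaction objective is the mean per-patient score, averaged over
replications (default 8 per evaluation, the study's recomputed replication
count).  Feasibility: total MR staffing ≤ A per period (A is likewise
unpublished and required configuration), nonnegative integers throughout.

Fuzzy normalization maps each objective onto [0, 1] between the extremes
found by the two single-objective runs; values outside the anchor interval
(possible since anchors come from separate stochastic runs) are clipped.
The weighted max–min achievement level is `λ = min(1, min_k f_k / w_k)`;
zero-weight objectives impose no constraint.  λ is the *search objective*,
recomputable exactly from the reported (Z_cost, Z_sat) — the replay test
asserts this identity.

The reference optimizer was a proprietary scatter-search tool; its moves
are unspecified.  This package's open reading: randomized ±1 moves on one
staffing entry around the incumbent, a 10 % chance of a uniform restart,
infeasible candidates rejected without simulation, stop after 100
consecutive evaluated candidates without improvement.  An `exhaustive`
proposal mode turns the same loop into brute-force enumeration, which the
tests use as the oracle on small lattices (≤ 200 feasible schedules).
Improvement is strict (> 1e−12), so ties keep the first-found candidate —
deterministic given the seed.

### Known inconsistency in the reference results

Replaying the bundled one-stop results with weights (0.8, 0.2): the printed
satisfaction value gives membership ≈ 0.157 < w_sat = 0.2, so no λ = 1 can
satisfy the weight constraints, yet λ = 1 is printed.  The replay flags
this row as inconsistent rather than passing it; the other 14
multi-objective rows replay to λ = 1 within 0.02.

## Statistics

* **Verification** — one old-status patient per type, deterministic service
  times, ample capacity: simulated LOS must equal the summed station means
  to 1e−9.  The type-3 sum is 2.6767 min, which rounds to 2.68, whereas the
  reference table prints 2.67 — a printing/rounding artifact in the source,
  kept visible rather than patched.
* **Validation** — Welch's unequal-variance t-test (hand-coded
  Welch–Satterthwaite, cross-checked against scipy in tests) of simulated
  LOS against reference (mean, SD, n) summaries; Welch rather than pooled
  because the reference per-type SDs differ substantially.
* **Replication sizing** — t-based 95 % CI half-width of a pilot, projected
  as 1/√n: `required_n = ceil(n0 (rel/target)²)` when the pilot misses the
  target, else the pilot size.  The study's own 10 → 8 reduction cannot be
  reproduced from printed data and is not asserted.
* **Comparison** — fixed-effects ANOVA (statsmodels OLS) with factors case
  and scenario, replication as a block, and the case×scenario interaction;
  a constant response reports F = 0, p = 1.  Tukey HSD on cell means uses
  the studentized range (Tukey–Kramer SE for unequal n); the compact letter
  display uses insert-and-absorb, so sharing a letter is exactly
  equivalent to a non-significant pairwise difference (property-tested).
* **Decision** — "unchanged" satisfaction means sharing ≥ 1 Tukey letter
  with the benchmark; cost compares exactly (costs are deterministic).  The
  nine-row guideline is a total lookup.  Case selection: find the letter
  group spanning the minimum acceptable score (or the nearest group above),
  take its cheapest row, then replace it with the cheapest cheaper row of
  any strictly higher-scoring group.

## What the synthetic world does and does not establish

The generator reproduces the published input laws exactly (arrival
segments, type mix, service laws, elicitations), but the staffing baseline,
cost coefficients, counter capacity A and raw replication responses of the
original department were never published.  Green tests therefore establish:
the flow logic (exact verification), the distributional fidelity of the
inputs (3σ recovery at n = 10⁵), classical queueing structure (pooling
dominance under common random numbers), the optimizer's correctness against
enumeration, the internal consistency of the fuzzy max–min arithmetic with
the published optima, and the decision machinery row for row.  They do
**not** establish the published simulated LOS means, the 5296.5 Baht/day
baseline cost, the 85.81 % baseline satisfaction, or the published optimal
schedules — all of which depend on the unpublished inputs and are treated
as bundled reference data only.

## Numerical choices

Time is float minutes since 05:00 (service laws in seconds are converted on
sampling).  Event ties break by insertion order.  Verification equality is
1e−9 min; search improvement 1e−12; type-mix rows must sum to 1 within
1e−9.  Seeds: every stream is a named child of the run seed
(`SeedSequence([seed, crc32(name)])`); per-replication seeds stay below
2³¹.
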