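# Methods

## The system being modelled

An inpatient discharge at a specialised cancer hospital is a multi-actor
paper-and-people workflow. The patient's clock starts when the specialist
signs the discharge order and stops when the patient leaves the room. Two
things must both finish before departure: the *medication pathway*
(prescription written → pharmacy prepares the discharge medication → a
porter carries it to the ward → the nurse phones the clinical pharmacist →
the pharmacist arrives and counsels the patient) and the *paperwork
pathway* (medical records closes the chart → a porter carries the file to
accounting → the family settles the bill once they arrive → the clearance
sheet returns to the ward). Patients with extra needs add branches: an
outpatient narcotics prescription (~40% of patients), equipment procurement
through a social worker (~16%), a supplies purchase that requires the family
to open an outpatient file at the clinic — only possible once the inpatient
file is closed (~5%), and an add-on medication that repeats the medication
loop roughly 83 minutes after the first prescription (~16%). Total
discharge time is the completion of the last enabled branch, so parallel
branches absorb improvements made to other branches: that is why a
58-minute cut in pharmacy preparation shortens the *average* discharge by
far less than 58 minutes, and why the five interventions jointly save more
than the sum of their individual paired savings.

Patients whose discharge needs equipment, supplies or an add-on are called
*complex*; the rest are *standard*. This two-population structure is what
the duration histogram and the out-of-control points of the individuals
control chart reflect.

## Process model

The workflow is a DAG of activities. Each activity has a duration model
(Weibull, normal, lognormal, exponential, triangular or fixed — all in
minutes), an optional start offset, an optional need-flag condition, and an
optional resource demand served FIFO from a capacitated pool. Printed
parameters are embedded verbatim:

| quantity | value | where it enters |
|---|---|---|
| order → prescription gap | 38 min mean | `medication_order` |
| pharmacy preparation | 88 min mean | `pharmacy_preparation` |
| narcotics activity | 43 min mean | `narcotics_prescription` |
| equipment activity | 134 min mean | `equipment_arrangement` |
| supplies trip | 195 min mean | `supplies_outpatient_trip` |
| add-on lag | 83 min mean offset | `addon_medication_order` |
| medical records | Weibull(1.7374, 22.091) | `medical_records_processing` |
| family-arrival delay | Normal(1.1087, 1.43610), truncated | `accounting_family_wait` |
| accountant attention | Lognormal(2.39750, 2.24560) | `accounting_settlement` |

Normal and lognormal models are parameterised by the mean and SD of the
variate itself. Negative draws under truncation are *resampled*, not
clipped — clipping would pile mass at zero and bias means asymmetrically.
The accounting delay/attention parameters are interpreted literally in
minutes even though they look small for an accounting step; the observed
paperwork branch is short and never critical, so nothing downstream depends
on this choice.

Resource pools: 1 porter, 1 clinical pharmacist, 2 medical-records
officers, 2 accountants. The pharmacy itself is deliberately *not* a scarce
pool: the 88-minute preparation average is an end-to-end measured duration
that already contains pharmacy-internal queueing, and a literal 2-server
pharmacy serving 24 discharges/day at 88 min/job would be unstable
(offered load ≈ 4.4 erlangs). The porter and pharmacist pools, by
contrast, are modelled explicitly because two of the five interventions act
on exactly those resources.

Discharge orders arrive as a Poisson stream at 24/day (≈8,722 discharges a
year) concentrated in an 8-hour morning window, matching morning rounds.
The ward empties overnight, so there is no warm-up period; every patient
who arrives within the horizon is run to completion.

Need flags are independent Bernoulli draws at the observed frequencies
(0.40/0.16/0.05/0.16). Independence implies ≈33% complex patients, whereas
the study's own classification put the complex share near 20%; the flags
may well be correlated in reality, so a Gaussian-copula correlation knob is
exposed (`sample_profile(..., correlation=...)`), with independence as the
default.

## Simulation engine

A standard event-calendar core: a heap ordered by (time, insertion
sequence) — deterministic tie-breaking — FIFO seize/release on pools, and
per-patient routing over the profile-conditional precedence structure
(disabled conditional activities are spliced out, successors inheriting
their predecessors). No preemption; seizes run to completion.

All randomness is pre-sampled per replication from named substreams of a
counter-based generator (Philox), one stream per activity plus streams for
arrivals and profiles, keyed by (seed, replication, CRC of the element
name). Patient *i* consumes the *i*-th draw of each stream. Consequences:

* bitwise reproducibility for identical (graph, seed, horizon);
* common random numbers across scenarios for free — two graphs sharing
  activity names see identical draws wherever their duration models agree,
  so a no-op scenario has a paired delta of exactly zero;
* under ample resources, pointwise reduction of one activity's duration can
  only shorten discharges (tested property). Under FIFO *contention* this
  monotonicity is not a theorem — shorter service can reorder queue
  arrivals — so the property test runs with ample capacities.

The engine is verified against an independent deterministic oracle: with
every duration frozen at its mean and unbounded resources, each of the 16
need-profiles' totals must equal the topological longest-path time.

## Free parameters and calibration

Durations the study measured but never printed (porter legs, nurse call,
pharmacist arrival and counseling, clearance return, the add-on loop, and
several branch spreads) are free parameters with bounds. They are fitted by
simulated method of moments against the printed statistics: observed
baseline mean 215.7 ± 5 and SD 67 ± 12 minutes; paired reductions 36
(pharmacy fast track), 8.53 (extra porter), 21 (pharmacist transport), 4.2
(early equipment) and 7.36 (supplies to floor) minutes, each at ±25%
relative tolerance; and the combined reduction 115 ± 15 minutes. The
combined target is included because the single deltas alone do not pin down
the joint behaviour: the reported combined saving (115) far exceeds the sum
of the singles (77.1), which the model reproduces through two mechanisms —
single-scenario savings are diluted by parallel branches that remain
critical (notably the add-on loop and the equipment tail), and queue
congestion at the porter and pharmacist relaxes only when several
interventions are combined.

The search is coordinate descent with shrinking steps inside the bound box,
minimising a tolerance-normalised weighted quadratic loss. Objective
evaluations use 20 replications with a fixed common-random-number
substream, so the search is deterministic given its seed; the optimum is
re-evaluated afresh at a fuller replication count. A baseline mean outside
its tolerance raises a calibration-failure error rather than returning
silently. The fitted values ship in `data/calibrated_params.json`; tests
re-verify the achieved statistics and never re-run the search.

Scenario-side free parameters (the handover that replaces equipment
procurement after an early announcement, the on-floor supplies delivery,
and the pharmacist's combined transport-and-counsel time) are calibrated
jointly with the baseline parameters, since the corresponding printed
reductions are the only evidence about them.

## Scenarios

Declarative overrides on the baseline graph: duration replacement, capacity
delta, activity removal (predecessors spliced onto successors), resource
reassignment. Re-applying a scenario raises — capacity deltas accumulate,
so application is deliberately not idempotent. The pharmacist-transport
scenario removes the porter delivery, the nurse call and the arrival delay,
rewires counseling directly after pharmacy preparation, and also shortens
the add-on loop's delivery (the pharmacist carries that medication too).
The paired suite reports a Pareto-ordered table; percent-of-total-reduction
is defined over the five single interventions and sums to 100%.

## SPC layer

Individuals/moving-range charts use the span-2 constants (E2 = 2.66 =
3/1.128, D4 = 3.267); only the beyond-limits rule is applied, since run
rules are not used in the source analyses. Capability is the one-sided
normal model against an upper specification limit of 150 minutes:
`z_bench = (USL − μ)/σ`, `p_above = Φ̄(z_bench)`, and the sigma quality
level is `z_bench + 1.5` exactly (the conventional long-term shift). With
the observed moments (215.7, 67) this gives z ≈ −0.98; the −0.78 reported
from the Minitab capability analysis is not reproducible from those overall
moments alone (it likely used a within-subgroup sigma), so the package
treats the moments-based z as the defined computation, defaults to the
overall (long-term) SD, and keeps the SQL conversion — which *is* exact —
as the reference surface. A within-subgroup option (σ̂ = mrbar/1.128) is
available via the chart statistics.

Two-population classification uses profile flags when present; for bare
duration series it fits a two-component univariate Gaussian mixture by EM
with deterministic k-means initialisation (fixed random state) and labels
the lower-mean component standard. An all-identical series produces a
degenerate-fit warning and a single component. Bimodality of synthetic
data is checked by BIC preference for two components over one rather than
by a dip statistic — same scientific content with tooling available here.

## Synthetic shadowing data

Graph-driven mode simulates the calibrated model and keeps the first *n*
discharges (default 38, the study's usable sample), giving fully populated
per-activity timestamps. Summary mode draws totals from a two-population
truncated-normal mixture — standard ≈ N(185, 40), complex ≈ N(330, 70) at
an 80/20 mix, chosen so the pooled moments land near (215.7, 67); these
per-population values are declared assumptions stored in
`data/synthetic_defaults.json`, because the study printed only the pooled
moments and a histogram. An optional dropout rate mimics the three
cancelled shadowings (41 → 38); it is off by default. What passing tests on
synthetic data do *not* show: fidelity to any real hospital's activity-level
correlations, physician-dependent ordering variation, or measurement error
beyond simple dropout.

## Numerical and design choices

* Time unit: minutes everywhere; percentages reported to one decimal,
  minutes to two.
* Replication counts: 100 replications × one-month horizon for headline
  experiments (≈700 discharges per replication); 20 replications during
  calibration search; structural tests use 2–6 day horizons since they
  assert structure, not statistics.
* Simultaneous events: ordered by insertion sequence; FIFO queues grant the
  head of the line only (no overtaking by smaller requests).
* Engine limit: at most one resource pool per activity (the default graph
  needs no more); the validator reports anything else.
* `calibrate()` takes a graph *factory* (parameters → graph + scenarios)
  rather than a fixed graph, because scenario-delta targets require
  rebuilding the scenario configurations from the same parameter vector.

## What the calibrated model reproduces — and what it cannot

With the shipped configuration, 100-replication one-month experiments
reproduce the observed baseline (grand mean within ~1% of the reference
213.38/215.7 minutes; within-replication SD in the observed 67–76 range;
replication-mean SD ≈ 5), and four of the five paired intervention
reductions land within their ±25% calibration bands (extra porter,
pharmacist transport, early equipment announcement, supplies to floor).
Two quantities sit outside their bands, and the reason is structural, not a
fitting failure:

* **Fast track.** A 58-minute cut to pharmacy preparation propagates almost
  fully for the ~60% of patients whose medication branch is the critical
  path and who have no long parallel branch. The only branches that can
  absorb it are the add-on loop (16% of patients) and the equipment tail
  (16%, bounded by the small early-equipment saving). Those bound the
  attainable dilution at ~12–13 minutes, so the paired fast-track delta
  floors at ≈45 minutes against the reported 36. Values below ~45 would
  require a competing branch near the baseline critical path for *most*
  patients — which would then cap the combined scenario far above its
  reported 98 minutes.
* **Combined scenario.** The reported joint reduction (115 min) exceeds the
  sum of the five reported single reductions (77.1 min) by ~50%. In a
  model where total time is the completion of parallel branches, the
  paired joint reduction is bounded by what the five overrides remove from
  the critical path plus queue-relief interactions; that bound evaluates to
  ≈90–100 minutes here (achieved: ≈86, combined mean ≈130). The source
  describes its combined result as improvements "applied to all of the
  activities" — i.e. a programme including standardization, checklists and
  discharge planning beyond the five interventions it quantified
  individually — so the gap is attributed to improvements outside the
  modelled menu, and the combined-scenario calibration targets are
  reported as not met rather than forced by inflating other parameters
  beyond their bands.

The acceptance suite asserts each reproduction at its stated tolerance;
the two checks above are expected to fail for the reasons given, and are
left failing by design.

## Known limitations

* The model reproduces printed summary statistics, not the unpublished
  per-activity measurement table; the fitted free parameters are therefore
  a consistent — not unique — explanation of the printed numbers.
* FIFO queueing anomalies mean paired deltas for capacity changes can be
  slightly non-monotone at the patient level even though scenario-level
  means are stable.
* No upstream admission process, hospital geometry, or staff schedules;
  arrivals are a homogeneous morning-window Poisson stream.
* The capability analysis assumes normal totals; the actual mixture is
  right-skewed, so `p_above_usl` from moments understates the tail slightly.
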