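"""Event-driven execution of a :class:`~dischargesim.process.ProcessGraph`.

A classic three-phase discrete-event core: a time-ordered event calendar
(heap), FIFO resource pools with seize/release, and per-patient routing
through the precedence DAG.  Discharge orders arrive as a Poisson stream at
``arrivals_per_day`` concentrated in a morning window; every patient who
arrives within the horizon is run to completion (the ward empties overnight,
so there is no warm-up period to discard).

Common random numbers
---------------------
All stochastic draws are pre-sampled per replication from named substreams:
one stream per activity (keyed by a CRC of the activity name), plus streams
for arrivals and patient profiles.  Patient *i*'s duration for an activity
is the *i*-th draw of that activity's stream.  Two graphs that share
activity names therefore see identical draws wherever their duration models
agree, which makes paired scenario comparisons exact (a scenario with no
overrides reproduces the baseline bit for bit).

Simultaneous events are ordered by (time, insertion sequence) so runs are
deterministic given (graph, seed, horizon).
"""

from __future__ import annotations

import heapq
import zlib
from collections import deque
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .process import (
    ActivitySpec,
    PatientProfile,
    ProcessGraph,
    profiles_from_flags,
    sample_profiles_array,
    validate_graph,
)

MINUTES_PER_DAY = 1440.0


class SimulationError(RuntimeError):
    """Structural failure during a run (deadlock, invalid graph)."""


@dataclass
class DischargeRecord:
    patient_id: int
    profile: PatientProfile
    arrival_minute: float  # absolute clock minute of the discharge order
    log: Dict[str, Tuple[float, float]]  # activity -> (start, end), minutes from order
    total_minutes: float


@dataclass
class ReplicationSummary:
    n_discharges: int
    mean_minutes: float
    sd_minutes: float
    records: List[DischargeRecord]


@dataclass
class ExperimentSummary:
    n_replications: int
    grand_mean_minutes: float
    sd_of_replication_means: float
    replications: List[ReplicationSummary]

    @property
    def replication_means(self) -> np.ndarray:
        return np.array([r.mean_minutes for r in self.replications])


# ---------------------------------------------------------------------------
# profile-conditional graph views
# ---------------------------------------------------------------------------

def _enabled(act: ActivitySpec, key: Tuple[bool, bool, bool, bool]) -> bool:
    if act.condition is None:
        return True
    idx = {"narcotics": 0, "equipment": 1, "supplies": 2, "addon": 3}[act.condition]
    return key[idx]


def _effective_view(graph: ProcessGraph, key: Tuple[bool, bool, bool, bool]):
    """Precedence structure restricted to the activities a profile enables.

    Disabled activities are spliced out: their successors inherit their
    (recursively effective) predecessors.
    """
    acts = {a.name: a for a in graph.activities}
    enabled = {n: _enabled(a, key) for n, a in acts.items()}
    memo: Dict[str, frozenset] = {}

    def eff_preds(name: str) -> frozenset:
        if name in memo:
            return memo[name]
        out = set()
        for p in acts[name].predecessors:
            if enabled[p]:
                out.add(p)
            else:
                out |= eff_preds(p)
        memo[name] = frozenset(out)
        return memo[name]

    names = [n for n in acts if enabled[n]]
    preds = {n: eff_preds(n) for n in names}
    succs: Dict[str, List[str]] = {n: [] for n in names}
    for n in names:
        for p in preds[n]:
            succs[p].append(n)
    return names, preds, succs


# ---------------------------------------------------------------------------
# stream management
# ---------------------------------------------------------------------------

def _stream(seed: int, replication: int, tag: str) -> np.random.Generator:
    key = zlib.crc32(tag.encode()) & 0x7FFFFFFF
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, replication, key])))


def _presample(graph: ProcessGraph, seed: int, replication: int, n: int):
    """Draw per-activity duration and offset arrays for ``n`` patients."""
    durations: Dict[str, np.ndarray] = {}
    offsets: Dict[str, np.ndarray] = {}
    for a in graph.activities:
        rng = _stream(seed, replication, "act/" + a.name)
        durations[a.name] = np.asarray(a.duration.sample(rng, n), dtype=float)
        if a.start_offset is not None:
            rng_o = _stream(seed, replication, "off/" + a.name)
            offsets[a.name] = np.asarray(a.start_offset.sample(rng_o, n), dtype=float)
    return durations, offsets


def _sample_arrivals(graph: ProcessGraph, seed: int, replication: int, horizon_days: float):
    rng = _stream(seed, replication, "arrivals")
    times: List[float] = []
    day = 0
    while day < horizon_days:
        window = graph.day_window_minutes * min(1.0, horizon_days - day)
        k = rng.poisson(graph.arrivals_per_day * min(1.0, horizon_days - day))
        t = np.sort(rng.uniform(0.0, window, k)) + day * MINUTES_PER_DAY
        times.extend(t.tolist())
        day += 1
    return np.array(times)


# ---------------------------------------------------------------------------
# core run
# ---------------------------------------------------------------------------

def run_replication(
    graph: ProcessGraph,
    horizon_days: float,
    seed: int = 0,
    replication: int = 0,
) -> ReplicationSummary:
    """Simulate one horizon; every arriving patient is run to completion."""
    violations = validate_graph(graph)
    if violations:
        raise SimulationError("invalid graph: " + "; ".join(violations))
    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")

    arrivals = _sample_arrivals(graph, seed, replication, horizon_days)
    n = len(arrivals)
    flags = sample_profiles_array(graph.needs, _stream(seed, replication, "profiles"), n)
    profiles = profiles_from_flags(flags)

    durations, offsets = _presample(graph, seed, replication, n)
    acts = {a.name: a for a in graph.activities}
    views = {}  # profile key -> (names, preds, succs)

    pools: Dict[str, dict] = {
        r.name: {"cap": r.capacity, "free": r.capacity, "queue": deque()} for r in graph.resources
    }

    # per-patient state
    remaining: List[Dict[str, int]] = []
    logs: List[Dict[str, Tuple[float, float]]] = [dict() for _ in range(n)]
    done = [False] * n

    heap: List[Tuple[float, int, int, int, str]] = []
    seq = 0

    def push(t: float, kind: int, pid: int, act: str) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, pid, act))
        seq += 1

    # kinds: 0 = activity becomes ready, 1 = activity ends
    def on_ready(t: float, pid: int, act: str) -> None:
        spec = acts[act]
        if spec.resources:
            pool_name, count = spec.resources[0]
            pool = pools[pool_name]
            pool["queue"].append((pid, act, count))
            try_grant(t, pool_name)
        else:
            start(t, pid, act)

    def try_grant(t: float, pool_name: str) -> None:
        pool = pools[pool_name]
        while pool["queue"] and pool["queue"][0][2] <= pool["free"]:
            pid, act, count = pool["queue"].popleft()
            pool["free"] -= count
            start(t, pid, act)

    def start(t: float, pid: int, act: str) -> None:
        dur = durations[act][pid]
        logs[pid][act] = (t - arrivals[pid], t - arrivals[pid] + dur)
        push(t + dur, 1, pid, act)

    def on_end(t: float, pid: int, act: str) -> None:
        spec = acts[act]
        if spec.resources:
            pool_name, count = spec.resources[0]
            pools[pool_name]["free"] += count
            try_grant(t, pool_name)
        if act == graph.end_activity:
            done[pid] = True
            return
        key = profiles[pid].key()
        _, preds, succs = views[key]
        for s in succs[act]:
            remaining[pid][s] -= 1
            if remaining[pid][s] == 0:
                off = offsets.get(s)
                delay = float(off[pid]) if off is not None else 0.0
                if delay > 0.0:
                    push(t + delay, 0, pid, s)
                else:
                    on_ready(t, pid, s)

    # seed the calendar with discharge-order arrivals
    source = next(a.name for a in graph.activities if not a.predecessors)
    for pid, t0 in enumerate(arrivals):
        key = profiles[pid].key()
        if key not in views:
            views[key] = _effective_view(graph, key)
        names, preds, _ = views[key]
        remaining.append({m: len(preds[m]) for m in names})
        push(float(t0), 0, pid, source)

    while heap:
        t, _, kind, pid, act = heapq.heappop(heap)
        if kind == 0:
            on_ready(t, pid, act)
        else:
            on_end(t, pid, act)

    if not all(done):
        blocked = sorted(
            {a for pid in range(n) if not done[pid]
             for a, r in remaining[pid].items() if r > 0 and a not in logs[pid]}
        )
        raise SimulationError(f"deadlock: patients pending with blocked activities {blocked}")

    records = [
        DischargeRecord(
            patient_id=pid,
            profile=profiles[pid],
            arrival_minute=float(arrivals[pid]),
            log=logs[pid],
            total_minutes=logs[pid][graph.end_activity][1],
        )
        for pid in range(n)
    ]
    totals = np.array([r.total_minutes for r in records])
    return ReplicationSummary(
        n_discharges=n,
        mean_minutes=float(totals.mean()) if n else float("nan"),
        sd_minutes=float(totals.std(ddof=1)) if n > 1 else 0.0,
        records=records,
    )


def run_experiment(
    graph: ProcessGraph,
    n_replications: int,
    horizon_days: float = 30.0,
    seed: int = 0,
    keep_records: bool = False,
) -> ExperimentSummary:
    """Independent replications; replication ``r`` uses substream (seed, r)."""
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    reps = []
    for r in range(n_replications):
        summary = run_replication(graph, horizon_days, seed=seed, replication=r)
        if not keep_records:
            summary.records = []
        reps.append(summary)
    means = np.array([r.mean_minutes for r in reps])
    return ExperimentSummary(
        n_replications=n_replications,
        grand_mean_minutes=float(means.mean()),
        sd_of_replication_means=float(means.std(ddof=1)) if n_replications > 1 else 0.0,
        replications=reps,
    )


# ---------------------------------------------------------------------------
# deterministic oracle & validation arithmetic
# ---------------------------------------------------------------------------

def longest_path_time(graph: ProcessGraph, profile: PatientProfile) -> float:
    """Critical-path completion time with every duration at its mean.

    Ignores resource contention; topological dynamic programming over the
    profile's enabled activities.  Serves as the independent oracle for the
    event engine in degenerate (fixed-at-mean) mode.
    """
    violations = validate_graph(graph)
    if any("cycle" in v for v in violations):
        raise SimulationError("invalid graph: " + "; ".join(v for v in violations if "cycle" in v))
    key = profile.key()
    names, preds, succs = _effective_view(graph, key)
    acts = {a.name: a for a in graph.activities}
    finish: Dict[str, float] = {}
    remaining = {m: len(preds[m]) for m in names}
    stack = [m for m in names if remaining[m] == 0]
    while stack:
        m = stack.pop()
        spec = acts[m]
        ready = max((finish[p] for p in preds[m]), default=0.0)
        off = spec.start_offset.mean() if spec.start_offset is not None else 0.0
        finish[m] = ready + off + spec.duration.mean()
        for s in succs[m]:
            remaining[s] -= 1
            if remaining[s] == 0:
                stack.append(s)
    return finish[graph.end_activity]


def relative_error(observed: float, simulated: float) -> float:
    """Validation error, percent: 100 * (observed - simulated) / observed."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return round(100.0 * (observed - simulated) / observed, 2)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[DischargeRecord], activities: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One row per patient: id, need flags, per-activity start/end, total."""
    if activities is None:
        seen: List[str] = []
        for r in records:
            for a in r.log:
                if a not in seen:
                    seen.append(a)
        activities = seen
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "needs_narcotics": r.profile.needs_narcotics,
            "needs_equipment": r.profile.needs_equipment,
            "needs_supplies": r.profile.needs_supplies,
            "gets_addon": r.profile.gets_addon,
            "population": r.profile.population,
            "arrival_minute": r.arrival_minute,
            "total_minutes": r.total_minutes,
        }
        for a in activities:
            s, e = r.log.get(a, (np.nan, np.nan))
            row[f"{a}_start"] = s
            row[f"{a}_end"] = e
        rows.append(row)
    return pd.DataFrame(rows)


def write_records_csv(records: Sequence[DischargeRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_records_csv(path: str) -> List[DischargeRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    act_names = [c[: -len("_start")] for c in df.columns if c.endswith("_start")]
    out: List[DischargeRecord] = []
    for _, row in df.iterrows():
        prof = PatientProfile(
            int(row["patient_id"]),
            bool(row["needs_narcotics"]),
            bool(row["needs_equipment"]),
            bool(row["needs_supplies"]),
            bool(row["gets_addon"]),
        )
        log = {}
        for a in act_names:
            s, e = row[f"{a}_start"], row[f"{a}_end"]
            if pd.notna(s):
                log[a] = (float(s), float(e))
        out.append(
            DischargeRecord(
                patient_id=int(row["patient_id"]),
                profile=prof,
                arrival_minute=float(row.get("arrival_minute", 0.0)),
                log=log,
                total_minutes=float(row["total_minutes"]),
            )
        )
    return out
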