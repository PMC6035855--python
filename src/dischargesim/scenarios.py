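"""Improvement scenarios as declarative overrides of the baseline graph.

The five interventions evaluated in the study, plus their combination:

``fast_track``
    a pharmacy fast track: discharge-medication preparation takes a narrow
    30-minute model instead of the 88-minute average.
``extra_porter``
    one more porter in the pool.
``pharmacist_transport``
    the clinical pharmacist carries the medication up and counsels in one
    visit; the porter delivery, the nurse's phone call and the wait for the
    pharmacist's arrival disappear.
``early_equipment``
    equipment needs announced a day ahead; on the discharge day only a short
    handover remains.
``supplies_to_floor``
    supplies brought to the floor; the family's trip to the outpatient
    clinic is replaced by an on-floor delivery.
``all_improvements``
    all five applied together.

Scenario comparisons are paired with common random numbers: the suite runs
baseline and every scenario on the same seed schedule, so a scenario with no
overrides has a delta of exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Mapping, Optional, Sequence, Tuple

from .distributions import DurationModel, lognormal
from .engine import run_experiment
from .process import (
    ActivitySpec,
    ConfigError,
    ProcessGraph,
    ResourcePool,
    shipped_params,
    validate_graph,
)


@dataclass(frozen=True)
class Override:
    """One change to the baseline graph.

    kind:
      * ``duration``  — replace ``target`` activity's duration model
      * ``capacity``  — add ``delta`` servers to ``target`` resource pool
      * ``remove``    — delete ``target`` activity, splicing its
        predecessors onto its successors
      * ``resource``  — reassign ``target`` activity to another pool
    """

    kind: str
    target: str
    model: Optional[DurationModel] = None
    delta: int = 0
    pool: Optional[str] = None

    def field_key(self) -> Tuple[str, str]:
        # two overrides conflict when they touch the same field of the same target
        return ({"duration": "duration", "remove": "existence",
                 "resource": "resources", "capacity": "capacity"}[self.kind], self.target)


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    overrides: Tuple[Override, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for o in self.overrides:
            k = o.field_key()
            if k in seen:
                raise ConfigError(f"scenario {self.name!r}: conflicting overrides on {k}")
            seen.add(k)


@dataclass
class ScenarioResult:
    name: str
    mean_minutes: float
    delta_vs_baseline_minutes: float
    percent_of_total_reduction: Optional[float]
    sd_of_replication_means: float = float("nan")


def builtin_scenarios(params: Optional[Mapping[str, float]] = None) -> List[ScenarioConfig]:
    """The study's five single interventions plus their combination.

    ``params`` overrides the shipped calibrated values of the scenario-side
    free parameters (fast-track spread, handover, on-floor delivery,
    pharmacist transport-and-counsel time).
    """
    p = shipped_params()
    if params:
        p.update(params)
    fast_track = ScenarioConfig(
        "fast_track",
        (Override("duration", "pharmacy_preparation", model=lognormal(30.0, 5.0)),),
        "pharmacy fast track: 30-minute medication preparation",
    )
    extra_porter = ScenarioConfig(
        "extra_porter",
        (Override("capacity", "porter", delta=1),),
        "one additional porter",
    )
    pharmacist_transport = ScenarioConfig(
        "pharmacist_transport",
        (
            Override("remove", "porter_transport_medication"),
            Override("remove", "nurse_call_pharmacist"),
            Override("remove", "pharmacist_arrival"),
            Override(
                "duration", "pharmacist_counseling",
                model=lognormal(p["transport_counseling_mean"], 0.4 * p["transport_counseling_mean"]),
            ),
            # the repeat loop's delivery is carried by the pharmacist as well
            Override(
                "duration", "addon_delivery_counseling",
                model=lognormal(0.5 * p["transport_counseling_mean"],
                                0.2 * p["transport_counseling_mean"]),
            ),
        ),
        "clinical pharmacist transports the medication and counsels in one visit",
    )
    early_equipment = ScenarioConfig(
        "early_equipment",
        (Override("duration", "equipment_arrangement",
                  model=lognormal(p["handover_mean"], 0.4 * p["handover_mean"])),),
        "equipment announced a day earlier; only a handover remains",
    )
    supplies_to_floor = ScenarioConfig(
        "supplies_to_floor",
        (Override("duration", "supplies_outpatient_trip",
                  model=lognormal(p["onfloor_delivery_mean"], 0.4 * p["onfloor_delivery_mean"])),),
        "supplies delivered to the floor instead of the outpatient clinic",
    )
    combined = ScenarioConfig(
        "all_improvements",
        fast_track.overrides
        + extra_porter.overrides
        + pharmacist_transport.overrides
        + early_equipment.overrides
        + supplies_to_floor.overrides,
        "all five improvements applied together",
    )
    return [fast_track, extra_porter, pharmacist_transport, early_equipment, supplies_to_floor, combined]


def apply_scenario(graph: ProcessGraph, scenario: ScenarioConfig) -> ProcessGraph:
    """Return a new graph with the scenario's overrides applied.

    Not idempotent: capacity deltas accumulate, so re-applying a scenario
    that is already present raises a :class:`ConfigError`.
    """
    if scenario.name in graph.applied_scenarios:
        raise ConfigError(f"scenario {scenario.name!r} already applied to this graph")

    acts: List[ActivitySpec] = list(graph.activities)
    pools: List[ResourcePool] = list(graph.resources)
    names = {a.name for a in acts}
    pool_names = {r.name for r in pools}

    for o in scenario.overrides:
        if o.kind == "capacity":
            if o.target not in pool_names:
                raise ConfigError(f"override targets unknown resource {o.target!r}")
            pools = [
                replace(r, capacity=r.capacity + o.delta) if r.name == o.target else r
                for r in pools
            ]
        elif o.kind == "duration":
            if o.target not in names:
                raise ConfigError(f"override targets unknown activity {o.target!r}")
            if o.model is None:
                raise ConfigError(f"duration override on {o.target!r} lacks a model")
            acts = [replace(a, duration=o.model) if a.name == o.target else a for a in acts]
        elif o.kind == "resource":
            if o.target not in names:
                raise ConfigError(f"override targets unknown activity {o.target!r}")
            if o.pool is not None and o.pool not in pool_names:
                raise ConfigError(f"override reroutes to unknown pool {o.pool!r}")
            new_res = () if o.pool is None else ((o.pool, 1),)
            acts = [replace(a, resources=new_res) if a.name == o.target else a for a in acts]
        elif o.kind == "remove":
            if o.target not in names:
                raise ConfigError(f"override removes unknown activity {o.target!r}")
            victim = next(a for a in acts if a.name == o.target)
            spliced = []
            for a in acts:
                if a.name == o.target:
                    continue
                if o.target in a.predecessors:
                    preds = (a.predecessors - {o.target}) | victim.predecessors
                    a = replace(a, predecessors=preds)
                spliced.append(a)
            acts = spliced
            names.discard(o.target)
        else:
            raise ConfigError(f"unknown override kind {o.kind!r}")

    out = replace(
        graph,
        activities=acts,
        resources=pools,
        applied_scenarios=graph.applied_scenarios + (scenario.name,),
    )
    violations = validate_graph(out)
    if violations:
        raise ConfigError(f"scenario {scenario.name!r} produced an invalid graph: "
                          + "; ".join(violations))
    return out


def run_scenario_suite(
    graph: ProcessGraph,
    scenarios: Sequence[ScenarioConfig],
    n_replications: int = 100,
    seed: int = 0,
    horizon_days: float = 30.0,
) -> List[ScenarioResult]:
    """Paired comparison of scenarios against the baseline.

    The baseline and every scenario run on the same seed schedule (common
    random numbers).  Results are sorted by delta, largest first (Pareto
    order), with the baseline row first; percent_of_total_reduction is
    reported for single interventions (it sums to 100 across them) and is
    None for the baseline and any combined scenario.
    """
    base = run_experiment(graph, n_replications, horizon_days, seed)
    results = [ScenarioResult("baseline", base.grand_mean_minutes, 0.0, None,
                              base.sd_of_replication_means)]
    rows = []
    for sc in scenarios:
        g2 = apply_scenario(graph, sc)
        exp = run_experiment(g2, n_replications, horizon_days, seed)
        rows.append((sc, exp))

    single_total = sum(
        base.grand_mean_minutes - exp.grand_mean_minutes
        for sc, exp in rows
        if sc.name != "all_improvements"
    )
    scen_results = []
    for sc, exp in rows:
        delta = base.grand_mean_minutes - exp.grand_mean_minutes
        pct = (
            100.0 * delta / single_total
            if sc.name != "all_improvements" and single_total > 0
            else None
        )
        scen_results.append(
            ScenarioResult(sc.name, exp.grand_mean_minutes, delta, pct,
                           exp.sd_of_replication_means)
        )
    scen_results.sort(key=lambda r: -r.delta_vs_baseline_minutes)
    return results + scen_results
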