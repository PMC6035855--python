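"""Discharge-process data model.

The inpatient discharge workflow is represented as a DAG of activities.  A
patient's clock starts when the specialist signs the discharge order and
stops when the patient leaves the room.  Two main branches run in parallel
after the order is signed:

* the **medication branch** — prescription written, pharmacy preparation,
  porter delivery to the ward, nurse phones the clinical pharmacist, the
  pharmacist arrives and counsels the patient;
* the **paperwork branch** — medical-records processing, porter carries the
  file to accounting, the family settles the bill, clearance returns to the
  ward.

Patients with extra needs trigger conditional branches: a narcotics
prescription, equipment procurement, a supplies trip to the outpatient
clinic (only possible once the file is closed), or an add-on medication that
repeats the medication loop.  Total discharge time is the completion of the
last enabled branch.

Printed process parameters (the 38-minute order-to-prescription gap, the
88-minute pharmacy preparation, the 43/134/195-minute need activities, the
83-minute add-on lag, the Weibull medical-records time and the
normal/lognormal accounting times) are embedded verbatim.  Durations that
were measured in the original study but never printed (porter legs, phone
call, pharmacist arrival, counseling, clearance return, add-on loop,
branch spreads) are free parameters; the shipped values come from the
calibration module (see :mod:`dischargesim.calibration`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import yaml

from .distributions import DurationModel, fixed, lognormal, normal, triangular, weibull

NEED_FLAGS = ("narcotics", "equipment", "supplies", "addon")


class ConfigError(ValueError):
    """Raised for malformed graph / scenario configuration."""


@dataclass(frozen=True)
class ResourcePool:
    """A FIFO-served staff pool (porter, pharmacist, ...)."""

    name: str
    capacity: int
    discipline: str = "FIFO"

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ConfigError(f"resource {self.name!r}: capacity must be >= 1")
        if self.discipline != "FIFO":
            raise ConfigError("only FIFO discipline is supported")


@dataclass(frozen=True)
class ActivitySpec:
    name: str
    duration: DurationModel
    resources: Tuple[Tuple[str, int], ...] = ()
    predecessors: frozenset = frozenset()
    start_offset: Optional[DurationModel] = None
    condition: Optional[str] = None  # need flag gating the activity
    performer_note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "predecessors", frozenset(self.predecessors))
        object.__setattr__(self, "resources", tuple((str(p), int(c)) for p, c in self.resources))
        if self.condition is not None and self.condition not in NEED_FLAGS:
            raise ConfigError(f"activity {self.name!r}: unknown condition {self.condition!r}")


@dataclass(frozen=True)
class NeedProbabilities:
    """Frequencies of patient extra needs observed during shadowing."""

    p_narcotics: float = 0.40
    p_equipment: float = 0.16
    p_supplies: float = 0.05
    p_addon: float = 0.16

    def __post_init__(self) -> None:
        for f in ("p_narcotics", "p_equipment", "p_supplies", "p_addon"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f} must lie in [0, 1], got {v}")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.p_narcotics, self.p_equipment, self.p_supplies, self.p_addon)


@dataclass(frozen=True)
class PatientProfile:
    id: int
    needs_narcotics: bool
    needs_equipment: bool
    needs_supplies: bool
    gets_addon: bool

    @property
    def population(self) -> str:
        """'complex' iff the patient needs equipment, supplies or an add-on."""
        if self.needs_equipment or self.needs_supplies or self.gets_addon:
            return "complex"
        return "standard"

    def flag(self, name: str) -> bool:
        return getattr(self, {"narcotics": "needs_narcotics",
                              "equipment": "needs_equipment",
                              "supplies": "needs_supplies",
                              "addon": "gets_addon"}[name])

    def key(self) -> Tuple[bool, bool, bool, bool]:
        return (self.needs_narcotics, self.needs_equipment, self.needs_supplies, self.gets_addon)


@dataclass
class ProcessGraph:
    activities: List[ActivitySpec]
    resources: List[ResourcePool]
    needs: NeedProbabilities = field(default_factory=NeedProbabilities)
    arrivals_per_day: float = 24.0
    day_window_minutes: float = 480.0
    end_activity: str = "patient_departure"
    applied_scenarios: Tuple[str, ...] = ()

    def activity(self, name: str) -> ActivitySpec:
        for a in self.activities:
            if a.name == name:
                return a
        raise KeyError(name)

    def activity_names(self) -> List[str]:
        return [a.name for a in self.activities]

    def resource(self, name: str) -> ResourcePool:
        for r in self.resources:
            if r.name == name:
                return r
        raise KeyError(name)

    def replace_activity(self, name: str, new: ActivitySpec) -> "ProcessGraph":
        acts = [new if a.name == name else a for a in self.activities]
        return replace(self, activities=acts)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "resources": [
                {"name": r.name, "capacity": r.capacity, "discipline": r.discipline}
                for r in self.resources
            ],
            "activities": [
                {
                    "name": a.name,
                    "duration": a.duration.to_dict(),
                    **({"resources": [[p, c] for p, c in a.resources]} if a.resources else {}),
                    **({"predecessors": sorted(a.predecessors)} if a.predecessors else {}),
                    **({"start_offset": a.start_offset.to_dict()} if a.start_offset else {}),
                    **({"condition": a.condition} if a.condition else {}),
                    **({"performer_note": a.performer_note} if a.performer_note else {}),
                }
                for a in self.activities
            ],
            "needs": {
                "p_narcotics": self.needs.p_narcotics,
                "p_equipment": self.needs.p_equipment,
                "p_supplies": self.needs.p_supplies,
                "p_addon": self.needs.p_addon,
            },
            "arrivals": {
                "per_day": self.arrivals_per_day,
                "day_window_minutes": self.day_window_minutes,
            },
            "end_activity": self.end_activity,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProcessGraph":
        try:
            resources = [
                ResourcePool(r["name"], int(r["capacity"]), r.get("discipline", "FIFO"))
                for r in d.get("resources", [])
            ]
            activities = [
                ActivitySpec(
                    name=a["name"],
                    duration=DurationModel.from_dict(a["duration"]),
                    resources=tuple((p, int(c)) for p, c in a.get("resources", [])),
                    predecessors=frozenset(a.get("predecessors", [])),
                    start_offset=(
                        DurationModel.from_dict(a["start_offset"]) if "start_offset" in a else None
                    ),
                    condition=a.get("condition"),
                    performer_note=a.get("performer_note", ""),
                )
                for a in d["activities"]
            ]
            arrivals = d.get("arrivals", {})
            return cls(
                activities=activities,
                resources=resources,
                needs=NeedProbabilities(**d.get("needs", {})),
                arrivals_per_day=float(arrivals.get("per_day", 24.0)),
                day_window_minutes=float(arrivals.get("day_window_minutes", 480.0)),
                end_activity=d.get("end_activity", "patient_departure"),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed process-graph configuration: {exc}") from exc

    def save(self, path: str) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path: str) -> "ProcessGraph":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        g = cls.from_dict(d)
        violations = validate_graph(g)
        if violations:
            raise ConfigError("invalid graph: " + "; ".join(violations))
        return g


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_graph(g: ProcessGraph) -> List[str]:
    """Return a list of invariant violations (empty list = valid graph).

    Violations are returned as data rather than raised so a configuration
    loader can report all of them at once.
    """
    out: List[str] = []
    names = g.activity_names()
    seen = set()
    for n in names:
        if n in seen:
            out.append(f"duplicate activity name {n!r}")
        seen.add(n)
    name_set = set(names)
    pool_names = {r.name for r in g.resources}

    for a in g.activities:
        if a.name in a.predecessors:
            out.append(f"activity {a.name!r} references itself as predecessor")
        for p in a.predecessors:
            if p not in name_set:
                out.append(f"activity {a.name!r}: unresolved predecessor {p!r}")
        for pool, count in a.resources:
            if pool not in pool_names:
                out.append(f"activity {a.name!r}: unresolved resource {pool!r}")
            elif count > g.resource(pool).capacity:
                out.append(
                    f"activity {a.name!r}: requests {count} of {pool!r} "
                    f"(capacity {g.resource(pool).capacity})"
                )
        if len(a.resources) > 1:
            out.append(f"activity {a.name!r}: more than one resource pool is not supported")

    if g.end_activity not in name_set:
        out.append(f"end activity {g.end_activity!r} not in graph")

    sources = [a.name for a in g.activities if not a.predecessors]
    if len(sources) != 1:
        out.append(f"graph must have exactly one source activity, found {sorted(sources)}")

    # cycle detection by Kahn's algorithm on the precedence edges
    indeg = {n: 0 for n in name_set}
    succs: Dict[str, List[str]] = {n: [] for n in name_set}
    for a in g.activities:
        for p in a.predecessors:
            if p in name_set and p != a.name:
                indeg[a.name] += 1
                succs[p].append(a.name)
    queue = [n for n, d in indeg.items() if d == 0]
    done = 0
    while queue:
        n = queue.pop()
        done += 1
        for s in succs[n]:
            indeg[s] -= 1
            if indeg[s] == 0:
                queue.append(s)
    if done != len(name_set):
        cyc = sorted(n for n, d in indeg.items() if d > 0)
        out.append(f"cycle detected involving activities {cyc}")
    return out


# ---------------------------------------------------------------------------
# patient profiles
# ---------------------------------------------------------------------------

def sample_profile(
    needs: NeedProbabilities,
    rng: np.random.Generator,
    patient_id: int = 0,
    correlation: float = 0.0,
) -> PatientProfile:
    """Draw a patient's need flags.

    Flags are independent Bernoulli draws by default.  ``correlation`` > 0
    couples them through a Gaussian copula with common pairwise correlation,
    which lowers the complex-discharge share below the independence value
    (~33% at the default frequencies) toward the ~20% the shadowing study
    classified; independence is the default.
    """
    flags = sample_profiles_array(needs, rng, 1, correlation)[0]
    return PatientProfile(patient_id, *map(bool, flags))


def sample_profiles_array(
    needs: NeedProbabilities,
    rng: np.random.Generator,
    n: int,
    correlation: float = 0.0,
) -> np.ndarray:
    """Vectorised form of :func:`sample_profile`; returns an (n, 4) bool array."""
    probs = np.array(needs.as_tuple())
    if correlation == 0.0:
        return rng.random((n, 4)) < probs
    if not -1.0 / 3.0 < correlation < 1.0:
        raise ConfigError("correlation must lie in (-1/3, 1) for a 4-flag equicorrelated copula")
    from scipy import stats as _st

    cov = np.full((4, 4), correlation)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(4), cov, size=n, method="cholesky")
    u = _st.norm.cdf(z)
    return u < probs


def profiles_from_flags(flags: np.ndarray, start_id: int = 0) -> List[PatientProfile]:
    return [PatientProfile(start_id + i, *map(bool, row)) for i, row in enumerate(flags)]


# ---------------------------------------------------------------------------
# default graph
# ---------------------------------------------------------------------------

_DEFAULT_PARAMS_CACHE: Optional[Dict[str, float]] = None


def shipped_params() -> Dict[str, float]:
    """The shipped calibrated values of the free (unprinted) parameters."""
    global _DEFAULT_PARAMS_CACHE
    if _DEFAULT_PARAMS_CACHE is None:
        text = resources.files("dischargesim").joinpath("data/calibrated_params.json").read_text()
        _DEFAULT_PARAMS_CACHE = json.loads(text)["params"]
    return dict(_DEFAULT_PARAMS_CACHE)


#: bounds for every free parameter, minutes (or minutes of spread)
FREE_PARAM_BOUNDS: Dict[str, Tuple[float, float]] = {
    "sigma_order": (8.0, 30.0),
    "sigma_prep": (15.0, 45.0),
    "porter_transport_mean": (4.0, 15.0),
    "porter_file_mean": (3.0, 10.0),
    "nurse_call_mean": (2.0, 9.0),
    "pharmacist_arrival_mean": (5.0, 22.0),
    "counseling_mean": (6.0, 20.0),
    "clearance_mean": (3.0, 15.0),
    "addon_prep_mean": (15.0, 88.0),
    "addon_delivery_mean": (6.0, 50.0),
    "equipment_sigma": (40.0, 170.0),
    "supplies_sigma": (20.0, 90.0),
    "narcotics_sigma": (6.0, 30.0),
    "transport_counseling_mean": (12.0, 45.0),
    "handover_mean": (3.0, 15.0),
    "onfloor_delivery_mean": (10.0, 70.0),
}


def build_default_graph(
    params: Optional[Mapping[str, float]] = None,
    needs: Optional[NeedProbabilities] = None,
) -> ProcessGraph:
    """Build the study's discharge-process graph.

    ``params`` overrides individual free parameters; unspecified ones take
    the shipped calibrated values.  All printed parameters (38, 88, 43, 134,
    195, 83 minutes; W(1.7374, 22.091); N(1.1087, 1.43610);
    L(2.39750, 2.24560)) appear verbatim.
    """
    p = shipped_params()
    if params:
        unknown = set(params) - set(FREE_PARAM_BOUNDS)
        if unknown:
            raise ConfigError(f"unknown free parameters: {sorted(unknown)}")
        p.update(params)

    def ln(mean_key_or_value, sd) -> DurationModel:
        mean = p[mean_key_or_value] if isinstance(mean_key_or_value, str) else mean_key_or_value
        return lognormal(mean, sd)

    acts = [
        ActivitySpec(
            "discharge_order", fixed(0.0),
            performer_note="specialist signs the discharge order; time zero",
        ),
        # ----- medication branch -----
        ActivitySpec(
            "medication_order", ln(38.0, p["sigma_order"]),
            predecessors={"discharge_order"},
            performer_note="gap until the physician writes the medication prescription",
        ),
        ActivitySpec(
            "pharmacy_preparation", ln(88.0, p["sigma_prep"]),
            predecessors={"medication_order"},
            performer_note="pharmacy prepares discharge medication (includes pharmacy-internal queue)",
        ),
        ActivitySpec(
            "porter_transport_medication", ln("porter_transport_mean", 0.35 * p["porter_transport_mean"]),
            resources=(("porter", 1),),
            predecessors={"pharmacy_preparation"},
            performer_note="porter carries medication from pharmacy to the nurses' station",
        ),
        ActivitySpec(
            "nurse_call_pharmacist", triangular(1.0, p["nurse_call_mean"], 2.5 * p["nurse_call_mean"]),
            predecessors={"porter_transport_medication"},
            performer_note="nurse phones the clinical pharmacist",
        ),
        ActivitySpec(
            "pharmacist_arrival", ln("pharmacist_arrival_mean", 0.6 * p["pharmacist_arrival_mean"]),
            predecessors={"nurse_call_pharmacist"},
            performer_note="delay until the clinical pharmacist reaches the ward",
        ),
        ActivitySpec(
            "pharmacist_counseling", ln("counseling_mean", 0.4 * p["counseling_mean"]),
            resources=(("clinical_pharmacist", 1),),
            predecessors={"pharmacist_arrival"},
            performer_note="medication counseling at the bedside",
        ),
        # ----- paperwork branch -----
        ActivitySpec(
            "medical_records_processing", weibull(1.7374, 22.091),
            resources=(("medical_records", 1),),
            predecessors={"discharge_order"},
            performer_note="medical-records officer closes the chart",
        ),
        ActivitySpec(
            "file_to_accounting", ln("porter_file_mean", 0.35 * p["porter_file_mean"]),
            resources=(("porter", 1),),
            predecessors={"medical_records_processing"},
            performer_note="porter carries the file to accounting on the ground floor",
        ),
        ActivitySpec(
            "accounting_family_wait", normal(1.1087, 1.43610),
            predecessors={"file_to_accounting"},
            performer_note="file waits until the patient's family arrives at accounting",
        ),
        ActivitySpec(
            "accounting_settlement", lognormal(2.39750, 2.24560),
            resources=(("accountant", 1),),
            predecessors={"accounting_family_wait"},
            performer_note="accountant settles the bill with the family",
        ),
        ActivitySpec(
            "clearance_return", ln("clearance_mean", 0.4 * p["clearance_mean"]),
            resources=(("porter", 1),),
            predecessors={"accounting_settlement"},
            performer_note="porter returns the clearance sheet to the ward",
        ),
        # ----- conditional branches -----
        ActivitySpec(
            "narcotics_prescription", ln(43.0, p["narcotics_sigma"]),
            predecessors={"medication_order"},
            condition="narcotics",
            performer_note="outpatient controlled-drug prescription, family submits to pharmacy",
        ),
        ActivitySpec(
            "equipment_arrangement", ln(134.0, p["equipment_sigma"]),
            predecessors={"discharge_order"},
            condition="equipment",
            performer_note="social worker helps the family source equipment (oxygen generator, ...)",
        ),
        ActivitySpec(
            "supplies_outpatient_trip", ln(195.0, p["supplies_sigma"]),
            predecessors={"clearance_return", "pharmacist_counseling"},
            condition="supplies",
            performer_note="family opens an outpatient file and buys supplies at the clinic",
        ),
        ActivitySpec(
            "addon_medication_order", fixed(2.0),
            predecessors={"medication_order"},
            start_offset=lognormal(83.0, 25.0),
            condition="addon",
            performer_note="physician orders an add-on medication; the medication loop repeats",
        ),
        ActivitySpec(
            "addon_pharmacy_preparation", ln("addon_prep_mean", 0.4 * p["addon_prep_mean"]),
            predecessors={"addon_medication_order"},
            condition="addon",
            performer_note="pharmacy prepares the add-on medication",
        ),
        ActivitySpec(
            "addon_delivery_counseling", ln("addon_delivery_mean", 0.4 * p["addon_delivery_mean"]),
            predecessors={"addon_pharmacy_preparation"},
            condition="addon",
            performer_note="add-on delivered to the ward and counseled (composite of the repeat loop's delivery, call and counseling)",
        ),
        # ----- join -----
        ActivitySpec(
            "patient_departure", fixed(0.0),
            predecessors={
                "pharmacist_counseling",
                "clearance_return",
                "narcotics_prescription",
                "equipment_arrangement",
                "supplies_outpatient_trip",
                "addon_delivery_counseling",
            },
            performer_note="patient leaves the room once every enabled branch completes",
        ),
    ]
    pools = [
        ResourcePool("porter", 1),
        ResourcePool("clinical_pharmacist", 1),
        ResourcePool("medical_records", 2),
        ResourcePool("accountant", 2),
    ]
    g = ProcessGraph(activities=acts, resources=pools, needs=needs or NeedProbabilities())
    violations = validate_graph(g)
    if violations:  # pragma: no cover - construction guarantees validity
        raise ConfigError("; ".join(violations))
    return g
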