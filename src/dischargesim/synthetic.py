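"""Synthetic shadowing datasets.

The study's measurements came from shadowing 38 discharges over a month;
that data is not deposited anywhere, so this module generates per-patient
records with the same statistical structure, making every analytics stage
testable without external data.

Two modes:

* **graph-driven** (default): records come from simulating the calibrated
  process graph, so per-activity timestamps are populated and the totals
  inherit the full branch/queueing structure.
* **summary**: totals are drawn from a two-population truncated-normal
  mixture (standard vs. complex discharges) whose parameters live in
  ``data/synthetic_defaults.json`` — declared assumptions, since the
  per-population moments of the observed histogram were never printed.

The CSV schema matches the simulation engine's record export, so the SPC
layer consumes either interchangeably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .engine import DischargeRecord, run_replication, write_records_csv
from .process import (
    ConfigError,
    NeedProbabilities,
    PatientProfile,
    ProcessGraph,
    build_default_graph,
)


def summary_defaults() -> dict:
    text = resources.files("dischargesim").joinpath("data/synthetic_defaults.json").read_text()
    return json.loads(text)


@dataclass
class ShadowingConfig:
    n_patients: int = 38
    needs: NeedProbabilities = field(default_factory=NeedProbabilities)
    population_params: Optional[Mapping[str, Tuple[float, float]]] = None
    p_complex: Optional[float] = None
    graph: Optional[ProcessGraph] = None
    seed: int = 0
    dropout_rate: float = 0.0  # chance a shadowed discharge is cancelled

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.population_params is not None and self.graph is not None:
            raise ConfigError("choose summary mode or graph-driven mode, not both")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")


def generate_shadowing(
    config: ShadowingConfig, csv_path: Optional[str] = None
) -> List[DischargeRecord]:
    """Generate synthetic shadowing records; deterministic per seed.

    With a positive ``dropout_rate`` some shadowed discharges are cancelled
    (as happened to 3 of the study's 41), so fewer than ``n_patients``
    records may return.
    """
    if config.population_params is not None:
        records = _summary_mode(config)
    else:
        records = _graph_mode(config)
    if config.dropout_rate > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD809]))
        keep = rng.random(len(records)) >= config.dropout_rate
        records = [r for r, k in zip(records, keep) if k]
    if csv_path is not None:
        write_records_csv(records, csv_path)
    return records


def _graph_mode(config: ShadowingConfig) -> List[DischargeRecord]:
    graph = config.graph if config.graph is not None else build_default_graph()
    records: List[DischargeRecord] = []
    rep = 0
    while len(records) < config.n_patients:
        days = max(1.0, np.ceil(1.2 * config.n_patients / graph.arrivals_per_day))
        summary = run_replication(graph, days, seed=config.seed, replication=rep)
        records.extend(summary.records)
        rep += 1
        if rep > 50:  # pragma: no cover
            raise ConfigError("could not generate enough discharges; check arrival rate")
    records = records[: config.n_patients]
    return [
        DischargeRecord(i, PatientProfile(i, *r.profile.key()), r.arrival_minute,
                        r.log, r.total_minutes)
        for i, r in enumerate(records)
    ]


def _summary_mode(config: ShadowingConfig) -> List[DischargeRecord]:
    params = {k: (float(v["mean"]), float(v["sd"])) if isinstance(v, Mapping) else tuple(v)
              for k, v in config.population_params.items()}
    for pop in ("standard", "complex"):
        if pop not in params:
            raise ConfigError(f"population_params must define {pop!r}")
    defaults = summary_defaults()
    p_complex = config.p_complex if config.p_complex is not None else float(defaults["p_complex"])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5A7D]))
    n = config.n_patients
    is_complex = rng.random(n) < p_complex
    narc = rng.random(n) < config.needs.p_narcotics

    # complex patients carry at least one of the three complex-need flags,
    # drawn in proportion to the configured frequencies
    p3 = np.array([config.needs.p_equipment, config.needs.p_supplies, config.needs.p_addon])
    records: List[DischargeRecord] = []
    for i in range(n):
        if is_complex[i]:
            flags = rng.random(3) < p3
            while not flags.any():
                flags = rng.random(3) < p3
        else:
            flags = np.zeros(3, dtype=bool)
        profile = PatientProfile(i, bool(narc[i]), *map(bool, flags))
        mean, sd = params[profile.population]
        total = -1.0
        while total < 0.0:
            total = rng.normal(mean, sd) if sd > 0 else mean
        records.append(DischargeRecord(i, profile, 0.0, {}, float(total)))
    return records


def summarize_needs(records: List[DischargeRecord]) -> pd.DataFrame:
    """Per-need frequencies and added minutes.

    Frequency is the mean of the need flag; added minutes is the difference
    of conditional mean total durations (flagged minus unflagged), the
    shadowing study's way of attributing extra time to each need.
    """
    if not records:
        raise ValueError("no records to summarize")
    totals = np.array([r.total_minutes for r in records])
    rows = []
    for need, attr in [
        ("narcotics", "needs_narcotics"),
        ("equipment", "needs_equipment"),
        ("supplies", "needs_supplies"),
        ("addon", "gets_addon"),
    ]:
        mask = np.array([getattr(r.profile, attr) for r in records])
        freq = float(mask.mean())
        if mask.any() and (~mask).any():
            added = float(totals[mask].mean() - totals[~mask].mean())
        else:
            added = float("nan")
        rows.append({
            "need": need,
            "frequency": freq,
            "n_flagged": int(mask.sum()),
            "added_minutes": added,
        })
    return pd.DataFrame(rows)
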