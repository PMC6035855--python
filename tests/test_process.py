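import numpy as np
import pytest

from dischargesim.distributions import fixed, weibull
from dischargesim.process import (
    ActivitySpec,
    ConfigError,
    NeedProbabilities,
    PatientProfile,
    ProcessGraph,
    ResourcePool,
    build_default_graph,
    sample_profile,
    sample_profiles_array,
    validate_graph,
)
from dischargesim.engine import longest_path_time


REQUIRED_ACTIVITIES = [
    "discharge_order",
    "medication_order",
    "pharmacy_preparation",
    "porter_transport_medication",
    "pharmacist_counseling",
    "medical_records_processing",
    "file_to_accounting",
    "accounting_settlement",
    "clearance_return",
    "narcotics_prescription",
    "equipment_arrangement",
    "supplies_outpatient_trip",
    "patient_departure",
]


class TestDefaultGraph:
    def test_is_valid(self, default_graph):
        assert validate_graph(default_graph) == []

    def test_contains_required_activities(self, default_graph):
        names = set(default_graph.activity_names())
        for a in REQUIRED_ACTIVITIES:
            assert a in names

    def test_printed_parameters_verbatim(self, default_graph):
        g = default_graph
        assert g.activity("medical_records_processing").duration == weibull(1.7374, 22.091)
        assert g.activity("pharmacy_preparation").duration.mean() == pytest.approx(88.0)
        assert g.activity("medication_order").duration.mean() == pytest.approx(38.0)
        assert g.activity("narcotics_prescription").duration.mean() == pytest.approx(43.0)
        assert g.activity("equipment_arrangement").duration.mean() == pytest.approx(134.0)
        assert g.activity("supplies_outpatient_trip").duration.mean() == pytest.approx(195.0)
        assert g.activity("addon_medication_order").start_offset.mean() == pytest.approx(83.0)
        assert g.activity("accounting_family_wait").duration.params == (1.1087, 1.43610)
        assert g.activity("accounting_settlement").duration.params == (2.39750, 2.24560)

    def test_need_probability_defaults(self, default_graph):
        assert default_graph.needs.as_tuple() == (0.40, 0.16, 0.05, 0.16)

    def test_longest_path_brackets_observed_mean(self, default_graph):
        """Profile-weighted deterministic critical path lies around the
        observed 215.7-minute average (queueing and stochastic-max effects,
        absent in deterministic mode, account for the remainder)."""
        p = np.array(default_graph.needs.as_tuple())
        weighted = 0.0
        for i in range(16):
            bits = np.array([(i >> b) & 1 == 1 for b in range(4)])
            w = np.prod(np.where(bits, p, 1 - p))
            weighted += w * longest_path_time(default_graph, PatientProfile(0, *map(bool, bits)))
        assert 180 <= weighted <= 250

    def test_unknown_free_parameter_rejected(self):
        with pytest.raises(ConfigError):
            build_default_graph({"not_a_param": 1.0})


class TestValidation:
    def _toy(self, activities, resources=()):
        return ProcessGraph(
            activities=list(activities),
            resources=list(resources) or [ResourcePool("r", 1)],
            end_activity=activities[-1].name,
        )

    def test_cycle_detected(self):
        g = self._toy([
            ActivitySpec("src", fixed(1)),
            ActivitySpec("a", fixed(1), predecessors={"src", "b"}),
            ActivitySpec("b", fixed(1), predecessors={"a"}),
            ActivitySpec("end", fixed(0), predecessors={"b"}),
        ])
        violations = validate_graph(g)
        cyc = [v for v in violations if "cycle" in v]
        assert len(cyc) == 1 and "'a'" in cyc[0] and "'b'" in cyc[0]

    def test_unresolved_resource_reported(self):
        g = self._toy([
            ActivitySpec("src", fixed(1), resources=(("xray_tech", 1),)),
            ActivitySpec("end", fixed(0), predecessors={"src"}),
        ])
        assert any("xray_tech" in v and "unresolved resource" in v for v in validate_graph(g))

    def test_self_reference_and_missing_pred(self):
        g = self._toy([
            ActivitySpec("src", fixed(1)),
            ActivitySpec("end", fixed(0), predecessors={"end", "ghost", "src"}),
        ])
        v = validate_graph(g)
        assert any("references itself" in s for s in v)
        assert any("'ghost'" in s for s in v)

    def test_capacity_must_be_positive(self):
        with pytest.raises(ConfigError):
            ResourcePool("porter", 0)


class TestProfiles:
    def test_population_rule(self):
        assert PatientProfile(0, True, False, False, False).population == "standard"
        assert PatientProfile(0, False, True, False, False).population == "complex"
        assert PatientProfile(0, False, False, True, False).population == "complex"
        assert PatientProfile(0, False, False, False, True).population == "complex"

    def test_degenerate_probabilities(self, rng):
        zeros = NeedProbabilities(0, 0, 0, 0)
        ones = NeedProbabilities(1, 1, 1, 1)
        assert sample_profile(zeros, rng).population == "standard"
        assert sample_profile(ones, rng).population == "complex"

    def test_complex_share_matches_independence_closed_form(self, rng):
        """1 - (1-0.16)(1-0.05)(1-0.16) ~= 0.33 under independent flags."""
        flags = sample_profiles_array(NeedProbabilities(), rng, 100_000)
        complex_frac = (flags[:, 1:] .any(axis=1)).mean()
        expected = 1 - (1 - 0.16) * (1 - 0.05) * (1 - 0.16)
        assert complex_frac == pytest.approx(expected, abs=0.006)

    def test_correlation_knob_lowers_complex_share(self, rng):
        flags = sample_profiles_array(NeedProbabilities(), rng, 50_000, correlation=0.5)
        assert (flags[:, 1:].any(axis=1)).mean() < 0.30
        # marginals preserved
        assert flags[:, 0].mean() == pytest.approx(0.40, abs=0.02)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            NeedProbabilities(p_narcotics=1.2)


class TestSerialization:
    def test_yaml_round_trip_is_identity(self, default_graph, tmp_path):
        path = tmp_path / "graph.yaml"
        default_graph.save(str(path))
        loaded = ProcessGraph.load(str(path))
        assert loaded.to_dict() == default_graph.to_dict()
        assert loaded.activities == default_graph.activities
        assert loaded.resources == default_graph.resources
        assert loaded.needs == default_graph.needs

    def test_malformed_config_raises(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("activities:\n  - name: a\n")
        with pytest.raises(ConfigError):
            ProcessGraph.load(str(path))
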