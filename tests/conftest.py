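import numpy as np
import pytest

from dischargesim.process import NeedProbabilities, PatientProfile, build_default_graph


@pytest.fixture(scope="session")
def default_graph():
    return build_default_graph()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def all_profiles():
    """All 16 need-flag combinations."""
    out = []
    for i in range(16):
        bits = [(i >> b) & 1 == 1 for b in range(4)]
        out.append(PatientProfile(i, *bits))
    return out
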