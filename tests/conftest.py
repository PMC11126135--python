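"""Shared fixtures: protocols, literature relaxation sets, one default study."""

import pytest

from ivimfield import SequenceProtocol, StudyConfig, load_relaxation_set, simulate_study


@pytest.fixture(scope="session")
def protocol():
    return SequenceProtocol.study_default()


@pytest.fixture(scope="session")
def relax055():
    return load_relaxation_set("calf_0.55T")


@pytest.fixture(scope="session")
def relax7():
    return load_relaxation_set("calf_7T")


@pytest.fixture(scope="session")
def relax7_table():
    return load_relaxation_set("calf_7T_table")


@pytest.fixture(scope="session")
def weights055(relax055, protocol):
    return relax055.weights(protocol)


@pytest.fixture(scope="session")
def weights7(relax7, protocol):
    return relax7.weights(protocol)


@pytest.fixture(scope="session")
def default_study():
    """One seeded default-condition study, shared by all tests that need it."""
    return simulate_study(StudyConfig(seed=0))
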