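import pytest
from hypothesis import HealthCheck, settings

import oncovalue as ov

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    # the shared config fixture is immutable, so reuse across examples is safe
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def config() -> ov.ScoringConfig:
    return ov.ScoringConfig()


@pytest.fixture
def prosper() -> ov.TrialEvidence:
    return ov.builtin_fixture("prosper")


@pytest.fixture
def spartan() -> ov.TrialEvidence:
    return ov.builtin_fixture("spartan")


@pytest.fixture
def arches() -> ov.TrialEvidence:
    return ov.builtin_fixture("arches")


@pytest.fixture
def titan() -> ov.TrialEvidence:
    return ov.builtin_fixture("titan")


@pytest.fixture
def enza_dosing() -> ov.RegimenDosing:
    return ov.builtin_dosing("enzalutamide")


@pytest.fixture
def apa_dosing() -> ov.RegimenDosing:
    return ov.builtin_dosing("apalutamide")
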