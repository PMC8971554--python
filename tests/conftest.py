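import pytest

from osteosim import GeneratorProfile, generate_parameter_set
from osteosim.params import apply_override

from helpers import full_persistence_override


@pytest.fixture(scope="session")
def ps():
    """The synthetic default-style parameter set used across tests."""
    return generate_parameter_set(GeneratorProfile(seed=7))


@pytest.fixture(scope="session")
def ps_full_persistence(ps):
    """Same set with persistence forced to 1 (oracle-compatible)."""
    return apply_override(ps, full_persistence_override())
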