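import pytest

from thermolock.validation import (  # noqa: F401  (re-exported for tests)
    enumerate_lattice_states,
    enumeration_state_ids,
    lattice_state_index,
    lattice_toy_system,
)


@pytest.fixture(scope="session")
def toy_system():
    return lattice_toy_system()
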