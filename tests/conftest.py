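import pytest

from karyograph.simulate import SimulationConfig, simulate_history


@pytest.fixture(scope="session")
def default_truth():
    """One default-parameter synthetic history shared across tests."""
    return simulate_history(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def quiet_truth():
    """A history with zero events: every genome equals the root."""
    rates = {"inversion": 0.0, "translocation": 0.0, "fusion": 0.0, "fission": 0.0}
    return simulate_history(SimulationConfig(seed=7, rates=rates))
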