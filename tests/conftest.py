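import pytest

from ciliascreen import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A scaled-down configuration that keeps every generator fast."""
    return SimulationConfig(
        seed=7,
        n_probes=2000,
        n_true_hits=50,
        universe_size=500,
        set_size=50,
        list_size=25,
        planted_overlap=5,
        n_cells=500,
    )
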