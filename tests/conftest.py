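import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lpvcfc.core import BandSpec, TimeSeries
from lpvcfc.simulate import SimulationSpec, generate_signal

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def set1_spec() -> SimulationSpec:
    """Reference monophasic simulation conditions: 4 Hz driver, 60 Hz carrier."""
    return SimulationSpec(coupling_set="I", seed=11)


@pytest.fixture(scope="session")
def set1_signal(set1_spec) -> TimeSeries:
    return generate_signal(set1_spec)


@pytest.fixture(scope="session")
def coupled_bands() -> tuple[BandSpec, BandSpec]:
    """The (phase, amplitude) band pair carrying the simulated coupling."""
    return BandSpec(3.5, 4.5), BandSpec(59.0, 61.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
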