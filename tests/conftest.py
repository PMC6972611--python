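import numpy as np
import pytest
from hypothesis import settings

from llps_nmr import ScenarioConfig, SpeciationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def scenario() -> ScenarioConfig:
    """Reference study conditions: 3 mM total, binodal 0.43 / spinodal 0.71 mM."""
    return ScenarioConfig(seed=1)


@pytest.fixture
def titration_cfg() -> SpeciationConfig:
    return SpeciationConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
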