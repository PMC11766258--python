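import numpy as np
import pytest
from hypothesis import settings

from glomcode.io import StimulusProtocol
from glomcode.synthetic import SimConfig

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def protocol() -> StimulusProtocol:
    """Default acquisition: 10 Hz, 2 s baseline, 3 s stimulus, 13 s trial."""
    return StimulusProtocol(frame_rate=10.0, stim_onset=20, stim_offset=50, n_frames=130)


@pytest.fixture
def tiny_config() -> SimConfig:
    """Small but structurally complete simulation for fast tests."""
    return SimConfig(n_flies_per_species=3, n_glomeruli=5, n_trials=2, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
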