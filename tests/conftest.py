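import numpy as np
import pytest

from tatabend.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_config():
    """Archaeal-like two-state bending: unbent 0.25 / bent 0.49."""
    return SimulationConfig(
        n_states=2, state_E=(0.25, 0.49), dwell_means=(1.0, 0.5),
        frame_period_s=0.02, e_noise_sd=0.05, seed=42)


@pytest.fixture
def three_state_config():
    """Eukaryotic-like linear chain: unbent/intermediate/fully bent."""
    return SimulationConfig(
        n_states=3, state_E=(0.32, 0.60, 0.75), dwell_means=(0.24, 0.31, 0.44),
        topology="linear-three-state", frame_period_s=0.02, e_noise_sd=0.05,
        seed=42)
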