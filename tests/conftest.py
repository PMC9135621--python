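import numpy as np
import pytest

from ketsim.config import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """Desk-scale generative config used across module tests."""
    return SimConfig(
        grid_dims=(12, 12, 12),
        n_participants_per_group={"HC": 10, "ESZ": 8, "CHR-P": 6},
        n_ketamine=4,
        n_timepoints_per_run=60,
        rng_seed=1234,
    )
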