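import numpy as np
import pytest

from timbre import sessions


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def maze_session():
    """Noiseless synthetic 3-arm maze session shared across tests."""
    return sessions.generate_session("maze", seed=1)


@pytest.fixture(scope="session")
def small_maze_config():
    return sessions.MazeConfig(n_trials=18, n_electrodes=32, n_cells=150)
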