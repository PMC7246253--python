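import numpy as np
import pytest

from dnf_visearch.config import default_config, experiments_config


@pytest.fixture(scope="session")
def cfg():
    """Reduced-resolution configuration used throughout the suite."""
    return experiments_config()


@pytest.fixture(scope="session")
def cfg_full():
    return default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
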