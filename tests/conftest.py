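import numpy as np
import pytest

from thermopsf import load_config


@pytest.fixture(scope="session")
def cfg():
    """Bundled instrument parameter set (probe/pump/medium/scene/detection)."""
    return load_config()


@pytest.fixture(scope="session")
def scene(cfg):
    return cfg.scene


@pytest.fixture(scope="session")
def detection(cfg):
    return cfg.detection


@pytest.fixture(scope="session")
def z_grid():
    return np.linspace(-25.0, 25.0, 501)
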