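import numpy as np
import pytest

from sec.config import RunConfig
from sec.forgery_synth import make_forgery


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def simple_forgery():
    """256x256 anatomy-like image with an exact duplicated 48x48 patch."""
    img, mask, spec = make_forgery(1, 256, 256, "simple", region_size=(48, 48))
    return img, mask, spec


@pytest.fixture
def default_config():
    return RunConfig()
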