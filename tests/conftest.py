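import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
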