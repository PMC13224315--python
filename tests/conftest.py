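import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261002)


@pytest.fixture(scope="session")
def te_ms():
    # three-echo acquisition (ms)
    return np.array([12.2, 35.352, 58.504])
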