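import numpy as np
import pytest

from enamelpic import EnamelConfig, generate_field


@pytest.fixture(scope="session")
def default_truth():
    """The default synthetic enamel field, generated once per session."""
    return generate_field(EnamelConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
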