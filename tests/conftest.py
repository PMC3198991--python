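import numpy as np
import pytest

from xenoscan.fingerprint import default_config, load_reference


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def fp_config():
    return default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20111010)
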