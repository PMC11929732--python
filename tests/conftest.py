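import numpy as np
import pytest

from srcohort.indexing import default_spec_set
from srcohort.templates import default_registry
from srcohort.uids import UIDGenerator


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def uid_gen():
    return UIDGenerator(101)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def spec_set():
    return default_spec_set()
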