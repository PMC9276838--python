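import numpy as np
import pytest

from rfasim.geometry import build_leveen_electrode


@pytest.fixture(scope="session")
def electrode_30():
    return build_leveen_electrode(30.0, 10, 1.0)


@pytest.fixture(scope="session")
def electrode_40():
    return build_leveen_electrode(40.0, 12, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
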