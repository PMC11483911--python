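import numpy as np
import pytest

from cdicekit.config import PRESETS


@pytest.fixture(scope="session")
def default_run():
    """Default 1900 rpm run configuration (fluids, geometry, operating point)."""
    return PRESETS["default_1900rpm"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)
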