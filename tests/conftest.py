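import numpy as np
import pytest

from antctx.design import REFERENCE_P_ACCEPT, REFERENCE_P_JOINT


@pytest.fixture
def rng():
    return np.random.default_rng(20230811)


@pytest.fixture
def reference_rows():
    """Published acceptance and joint probabilities of the worked example."""
    return list(REFERENCE_P_ACCEPT), list(REFERENCE_P_JOINT)
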