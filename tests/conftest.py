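import numpy as np
import pytest

import hepatoca as hc


@pytest.fixture(scope="session")
def chain10():
    return hc.build_chain(10)


@pytest.fixture(scope="session")
def hex4():
    return hc.build_hex_lobule(4)


@pytest.fixture(scope="session")
def hex10():
    return hc.build_hex_lobule(10)


@pytest.fixture
def damage40(chain10):
    """N = 10 chain with the 4 sites nearest the CV stressed."""
    return hc.init_pericentral(
        chain10, hc.InitSpec("pericentral_count", stressed_count=4)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
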