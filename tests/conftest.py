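import numpy as np
import pytest

from chronobug.schedules import concat_schedules, make_schedule


@pytest.fixture(scope="session")
def ld186_5d():
    return make_schedule("LD18:6", span_days=5)


@pytest.fixture(scope="session")
def dd_12d():
    return make_schedule("DD", span_days=12)


@pytest.fixture(scope="session")
def ld_then_dd(ld186_5d, dd_12d):
    return concat_schedules(ld186_5d, dd_12d)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
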