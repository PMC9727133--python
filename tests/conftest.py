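import numpy as np
import pytest

from msynscreen.simulate import fixture_cohort


@pytest.fixture(scope="session")
def fixture_frame():
    return fixture_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230407)
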