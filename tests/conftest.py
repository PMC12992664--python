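import numpy as np
import pytest

from numprf.schedule import build_run
from numprf.tuning import canonical_hrf


@pytest.fixture(scope="session")
def visual_schedule():
    return build_run("visual")


@pytest.fixture(scope="session")
def auditory_schedule():
    return build_run("auditory")


@pytest.fixture(scope="session")
def hrf():
    return canonical_hrf(0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
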