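import numpy as np
import pytest

from rehabcoach.exercises import default_catalogue, recognizer_catalogue


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def rec_catalogue(catalogue):
    return recognizer_catalogue(catalogue)


@pytest.fixture(scope="session")
def arm_raises(catalogue):
    return next(d for d in catalogue if d.name == "arm raises")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
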