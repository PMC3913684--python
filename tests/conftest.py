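import numpy as np
import pytest
from hypothesis import settings

from circmine.core import Thresholds

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def th():
    return Thresholds()


@pytest.fixture
def rng():
    return np.random.default_rng(20140204)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])
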