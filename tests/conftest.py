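import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from simc.fragments import IsobaricGroup
from simc.histone import k27_r40, pentamethyl_pair

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def pair() -> IsobaricGroup:
    """The H3 K27-R40 pentamethyl isobaric pair."""
    return pentamethyl_pair()


@pytest.fixture
def iso_a():
    return k27_r40(3, 2)  # K27me3-K36me2


@pytest.fixture
def iso_b():
    return k27_r40(2, 3)  # K27me2-K36me3


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250921)
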