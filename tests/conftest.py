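import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stumpstoich.core import ELEMENTS, ElementProfile, StumpSample

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_profile(rng=None, base=None) -> ElementProfile:
    """A positive random (or fixed) 12-element profile."""
    if base is not None:
        return ElementProfile(dict(base))
    rng = rng or np.random.default_rng(0)
    return ElementProfile(
        {el: float(rng.uniform(0.1, 100.0)) for el in ELEMENTS})


def make_stump(stump_id="s1", age=1.0, erg=10.0, rng=None,
               profile=None) -> StumpSample:
    return StumpSample(stump_id, age, erg,
                       profile or make_profile(rng))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wood_profile():
    """A realistic early-decay pine wood profile (units as convention)."""
    return ElementProfile({
        "C": 50.0, "N": 0.08, "S": 0.01, "P": 30.0, "K": 120.0,
        "Na": 18.0, "Ca": 700.0, "Mg": 140.0, "Fe": 40.0, "Zn": 9.0,
        "Mn": 65.0, "Cu": 1.5})


@pytest.fixture
def beetle_profile():
    return ElementProfile({
        "C": 52.0, "N": 10.0, "S": 0.6, "P": 8000.0, "K": 8800.0,
        "Na": 2800.0, "Ca": 1900.0, "Mg": 1100.0, "Fe": 150.0,
        "Zn": 180.0, "Mn": 28.0, "Cu": 25.0})
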