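import numpy as np
import pytest
from hypothesis import settings

from motorcycle import RateSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def kif1a() -> RateSet:
    """Measured KIF1A rate set (saturating-ATP conditions)."""
    return RateSet()


@pytest.fixture
def short_run_rates() -> RateSet:
    """KIF1A-like rates with 10x faster weak-state detachment.

    Mean runs of ~70 steps keep ensemble tests fast while exercising the
    same kinetic race.
    """
    return RateSet(k_detach_weak=2.7)


@pytest.fixture
def hand_table():
    """The three-run worked example: y = {1, 2, 3} um, last run censored."""
    return np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0])
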