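import numpy as np
import pytest
from hypothesis import settings

from adcea.analysis import calibrate_start_age
from adcea.mortality import LifeTable
from adcea.parameters import load_basecase
from adcea.synthetic_data import make_synthetic_life_table

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lifetable() -> LifeTable:
    """Default synthetic Gompertz-Makeham life table."""
    return make_synthetic_life_table()


@pytest.fixture()
def basecase():
    return load_basecase()


@pytest.fixture(scope="session")
def calibrated(lifetable):
    """Base case with start age tuned so undiscounted LE matches 46.05 y.

    Session-scoped: treat as read-only, copy before mutating.
    """
    p = load_basecase()
    p.settings.start_age = calibrate_start_age(p, lifetable, 46.05)
    return p


def flat_lifetable(max_age: int = 50, min_age: int = 0) -> LifeTable:
    """Deterministic table: no deaths until certain death at max_age."""
    ages = np.arange(min_age, max_age + 1)
    qx = np.zeros(ages.size)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


@pytest.fixture()
def det_lifetable() -> LifeTable:
    return flat_lifetable(50)


def degenerate_parameters(p_response: float, p_disc: float, p_sustained: float,
                          annual_disc: float):
    """All-0/1 clinical pathway with no waning, for exact oracle comparisons."""
    p = load_basecase()
    p.settings.start_age = 38.0
    p.settings.retirement_age = 45.0
    p.settings.max_age = 50.0
    for arm in ("abrocitinib", "soc"):
        c = p.clinical.for_arm(arm)
        c.p_response_16w = p_response
        c.p_disc_16_52w = p_disc
        c.p_sustained_52w = p_sustained
        c.annual_disc_post52w = annual_disc
        # long-term rate == 1 disables waning; only valid with sustained == 1
        c.longterm_response_rate = 1.0 if p_sustained == 1.0 else 0.0
    return p
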