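import numpy as np
import pytest

from mablabel import (
    RateConstants,
    SystemState,
    build_channels,
    preset_rates,
)


@pytest.fixture(scope="session")
def similar_rates() -> RateConstants:
    """Rate set with comparable monovalent and bivalent binding."""
    return preset_rates("similar")


@pytest.fixture(scope="session")
def channels(similar_rates):
    return build_channels(similar_rates)


@pytest.fixture()
def rng() -> np.random.RandomState:
    return np.random.RandomState(20240817)


@pytest.fixture(scope="session")
def small_state() -> SystemState:
    """A small mixed state exercising every channel's reactants."""
    return SystemState(A_b=40, A_c=25, A_o=60, AR=12, ARR=7, R=500, A_s=100)


def random_states(rng: np.random.RandomState, n: int):
    """Random non-negative integer states for property checks."""
    counts = rng.randint(0, 2000, size=(n, 7))
    return [
        SystemState(A_b=int(c[0]), A_c=int(c[1]), A_o=int(c[2]),
                    AR=int(c[3]), ARR=int(c[4]), R=int(c[5]), A_s=int(c[6]))
        for c in counts
    ]
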