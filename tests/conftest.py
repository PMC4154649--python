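import numpy as np
import pytest

from pepflux.synthetic_data import make_toy_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_toy_fixtures()


@pytest.fixture(scope="session")
def toy1(fixtures):
    return fixtures["toy1"]


@pytest.fixture(scope="session")
def toy1c(fixtures):
    return fixtures["toy1c"]


@pytest.fixture(scope="session")
def ecc1(fixtures):
    return fixtures["ecc1"]


@pytest.fixture(scope="session")
def two_species(fixtures):
    return fixtures["two_species"]


def toy1_profile(v3: float) -> dict[str, float]:
    """TOY1 steady-state profile parameterized by its single free flux."""
    return {
        "upt": 1.0,
        "v1": v3,
        "v2": 1.0 - v3,
        "v3": v3,
        "v4": 1.0,
        "co2_ex": 1.0,
    }


@pytest.fixture(scope="session")
def toy1_truth():
    return toy1_profile(0.6)
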