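import numpy as np
import pytest

from fibrilkit.exchange import ExchangeParameters, SaturationScheme
from fibrilkit.presets import default_scheme, variant_parameters


@pytest.fixture(scope="session")
def scheme() -> SaturationScheme:
    """Default two-field, 15-offset, 700 ms saturation scheme."""
    return default_scheme()


@pytest.fixture(scope="session")
def wt_params() -> ExchangeParameters:
    return variant_parameters("wt")


@pytest.fixture(scope="session")
def small_scheme() -> SaturationScheme:
    """A cheap scheme for tests that refit many times."""
    return SaturationScheme(
        sat_time=0.7,
        rf_fields=(180.0, 350.0),
        offsets=tuple(np.linspace(30000.0, -30000.0, 7)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
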