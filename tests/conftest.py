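import numpy as np
import pytest
from hypothesis import settings

from crfrelease import DimensionlessParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def base_params() -> DimensionlessParams:
    """Thin-film reference condition used throughout the validation suite."""
    return DimensionlessParams(Dr=1.0, Vr=10.0, l=1.2, Ka=1.0, Kb=1.0)


@pytest.fixture
def film_field_params() -> DimensionlessParams:
    """Thick-coating condition with an active hydrolysis source."""
    return DimensionlessParams(Dr=0.1, Vr=3.0, l=2.0, Ka=1.0, Kb=1.0,
                               kappa=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
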