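import numpy as np
import pytest

from hairsentinel.cohort import CohortConfig, generate_cohort
from hairsentinel.indices import RDATable
from hairsentinel.preprocessing import default_encoding_spec


@pytest.fixture(scope="session")
def rda():
    return RDATable.default()


@pytest.fixture(scope="session")
def encoding_spec():
    return default_encoding_spec()


@pytest.fixture(scope="session")
def cohort100():
    return generate_cohort(100, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def seasonal_series():
    """sin(2*pi*t/30) + N(0, 0.1) noise over 200 days, seed 0."""
    gen = np.random.default_rng(0)
    n = 200
    t = np.arange(n)
    y = np.sin(2 * np.pi * t / 30) + gen.normal(0, 0.1, n)
    cov = gen.normal(0, 1, (n, 2))
    return y, cov
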