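import numpy as np
import pandas as pd
import pytest

from bsclock import SimulationConfig, simulate_cohort
from bsclock.io_formats import CpGIndex


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with clear age signal, shared across unit tests."""
    return simulate_cohort(
        SimulationConfig(n_samples=60, n_sites=300, n_causal=30, seed=3)
    )


@pytest.fixture
def tiny_index():
    return CpGIndex({"chr1": [100, 115, 130], "chr2": [50, 60]})


@pytest.fixture
def sample_table_4():
    return pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "age": [10.0, 25.0, 40.0, 70.0],
            "sex": ["male", "female", "female", "male"],
            "disease": ["normal", "leukemia", "lymphoma", "normal"],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
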