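import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from aptox import CohortConfig, extract_feature_table, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort configuration used across tests."""
    return CohortConfig(
        n_patients=8, grid_shape=(12, 12, 12), seed=42, calibration_n=100
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return extract_feature_table(small_cohort)
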