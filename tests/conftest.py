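import numpy as np
import pandas as pd
import pytest

from driversub.synthetic import SyntheticCohortConfig, generate_cohort
from driversub.types import OmicsMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticCohortConfig(seed=0))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every planted effect switched off."""
    return generate_cohort(SyntheticCohortConfig.null(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, layer="mrna_tpm", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(layer, pd.DataFrame(values, index=features, columns=samples))
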