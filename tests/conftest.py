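import numpy as np
import pytest

from prescriptome import CohortConfig, generate_cohort
from prescriptome.ingest import build_exposure_matrix
from prescriptome.synthetic import generate_reference_tables


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def reference_tables(default_config):
    return generate_reference_tables(default_config)


@pytest.fixture(scope="session")
def exposure_matrix(default_cohort):
    return build_exposure_matrix(default_cohort.patients, default_cohort.prescriptions)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A fast 300-patient cohort for end-to-end plumbing tests."""
    return CohortConfig(n_patients=300, n_cases=21, seed=77)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
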