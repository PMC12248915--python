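import numpy as np
import pytest

from hpmfm import AcquisitionConfig, CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact deterministic cohort shared across tests."""
    spec = CohortSpec(n_patients=6, lesions_per_patient=(1, 3), seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionConfig(noise_sigma=0.0)
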