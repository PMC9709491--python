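import numpy as np
import pytest

import dupsim


@pytest.fixture(scope="session")
def params():
    """Packaged default model parameters."""
    return dupsim.load_parameters()


@pytest.fixture(scope="session")
def cohort69():
    """Default 69-patient synthetic cohort (fixed seed)."""
    return dupsim.generate_cohort(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def patient():
    return dupsim.Patient(
        id=0, age=61.0, sex="male", baseline_utility=0.82, baseline_fd=10.0, ectopic=False
    )
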