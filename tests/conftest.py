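import numpy as np
import pytest

from fedcaps.synthetic_data import (
    FEDERATED_TYPE_CYCLE,
    PhantomSpec,
    generate_dataset,
    generate_phantom,
)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with a tumor: exact tissue intensities."""
    return generate_phantom(
        PhantomSpec(tumor_present=True, noise_sigma=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(
        PhantomSpec(tumor_present=True, noise_sigma=0.02, seed=5)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """40 phantoms, half with tumors, federated type mix."""
    return generate_dataset(
        40, 0.5, seed=11, type_cycle=FEDERATED_TYPE_CYCLE
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
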