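import pytest

from gasferm.config import RunConfig
from gasferm.fluxmodel import build_core_model
from gasferm.synthetic import default_physiologies, simulate_dataset


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def physiologies():
    """Balance-closed physiologies for the default 6-condition grid."""
    return default_physiologies()


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Small noise-free dataset for exact round-trip checks."""
    return simulate_dataset(noise_sd=0.0, seed=11, n_genes=300,
                            compute_maintenance=False)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-scale dataset with 2% measurement noise and planted DEGs."""
    return simulate_dataset(noise_sd=0.02, seed=7, n_genes=2000,
                            compute_maintenance=False)


@pytest.fixture()
def default_config():
    return RunConfig()
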