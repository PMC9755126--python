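import numpy as np
import pytest

from smilescw.dataset_io import apply_split, make_split
from smilescw.monte_carlo import OptimizerConfig
from smilescw.smiles_attributes import profile_dataset
from smilescw.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_panel():
    """A compact labelled synthetic panel for optimizer-level tests."""
    dataset, truth = generate_dataset(
        GeneratorConfig(n_molecules=80, noise_sd=0.3, seed=11), name="small"
    )
    labelled = apply_split(dataset, make_split(dataset, seed=3))
    return labelled, profile_dataset(labelled), truth


@pytest.fixture(scope="session")
def fast_config():
    return OptimizerConfig(T=1, n_epochs=4, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
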