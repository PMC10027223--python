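import numpy as np
import pytest

from combosyn.data import featurize_drugs
from combosyn.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """12 drugs x 3 cell lines, fully measured, fixed seed."""
    cfg = SimConfig(n_drugs=12, n_cell_lines=3, seed=7)
    dataset, truth = generate_dataset(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def small_fingerprints(small_dataset):
    dataset, _ = small_dataset
    return featurize_drugs(None, dataset.drugs, n_bits=32, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
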