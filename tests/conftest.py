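import numpy as np
import pytest

from ditptox.dataset_io import LabeledDataset, MoleculeRecord
from ditptox.synthetic_data import (
    SyntheticSpec,
    generate_feature_dataset,
    generate_smiles_fixture,
)


@pytest.fixture(scope="session")
def smiles_ds() -> LabeledDataset:
    """Hand-validated 24-molecule SMILES fixture."""
    return generate_smiles_fixture(24)


@pytest.fixture(scope="session")
def synthetic_default():
    """A 300-molecule synthetic dataset at the default study conditions:
    0.41 positive fraction, 3 planted alerts at 0.8/0.1, 1.5-sd descriptor
    shifts."""
    spec = SyntheticSpec(n_molecules=300, seed=11)
    return generate_feature_dataset(spec)


@pytest.fixture
def toy_ds() -> LabeledDataset:
    """30 molecules (12 pos / 18 neg) with dummy SMILES for split tests."""
    records = [
        MoleculeRecord(f"M{i:02d}", "C", 1 if i < 12 else 0) for i in range(30)
    ]
    return LabeledDataset(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
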