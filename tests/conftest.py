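import numpy as np
import pytest

from gsfl.config import ModelConfig
from gsfl.synthetic_fixtures import FixtureSpec, generate_toy_dataset


@pytest.fixture(scope="session")
def toy_records():
    """200 noise-free synthetic molecules at the 2:3 class ratio."""
    records, rule_labels = generate_toy_dataset(FixtureSpec(n_molecules=200, seed=11))
    return records


@pytest.fixture(scope="session")
def toy_smiles(toy_records):
    return [r.smiles for r in toy_records]


@pytest.fixture(scope="session")
def big_smiles():
    """1000 generated SMILES for property checks."""
    records, _ = generate_toy_dataset(FixtureSpec(n_molecules=1000, seed=23))
    return [r.smiles for r in records]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config():
    """Smallest config that still exercises every module; for training tests."""
    return ModelConfig(
        batch_size=8,
        learning_rate=1e-3,
        gnn_layers=1,
        seq_layers=1,
        gnn_hidden=16,
        seq_hidden=16,
        dropout=0.0,
        fusion_dim=16,
        max_len=48,
        epochs=2,
        patience=50,
        transformer_heads=2,
        seed=0,
    )
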