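import numpy as np
import pytest

from csnet import NetworkConfig, SyntheticSpec, generate_dataset, train_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Small strong-signal synthetic dataset: 60 coding + 60 noncoding."""
    spec = SyntheticSpec(n_coding=60, n_noncoding=60, length_range=(200, 500), seed=11)
    records, truth = generate_dataset(spec)
    return records, truth


@pytest.fixture(scope="session")
def small_classes(small_dataset):
    records, _ = small_dataset
    pos = [r for r in records if r.label == "lncRNA"]
    neg = [r for r in records if r.label == "mRNA"]
    return pos, neg


@pytest.fixture(scope="session")
def tiny_config():
    """Reduced network for fast tests (same architecture family)."""
    return NetworkConfig(n_filters=8, hidden_units=16, epochs=8,
                         batch_size=64, n_ensemble=1, seed=7)


@pytest.fixture(scope="session")
def tiny_ensemble(small_classes, tiny_config):
    pos, neg = small_classes
    return train_ensemble(pos, neg, tiny_config)
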