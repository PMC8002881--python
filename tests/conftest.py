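import numpy as np
import pytest

from cleavesite import encoding, model, synthetic


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small noise-free trypsin cohort for fast model-level tests."""
    cfg = synthetic.SimConfig(n_proteins=24, length_range=(60, 90), seed=11)
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_windows(tiny_dataset):
    provider = encoding.PrecomputedFeatureProvider(tiny_dataset.features)
    return encoding.encode_dataset(
        tiny_dataset.proteins, tiny_dataset.annotations, "trypsin", provider
    )


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return model.split_proteins([p.id for p in tiny_dataset.proteins], seed=3)


@pytest.fixture(scope="session")
def small_config():
    """Desk-test model config: tiny network, few epochs."""
    return model.ModelConfig(
        n_bilstm_layers=2,
        hidden_units=4,
        dense_units=8,
        learning_rate=5e-3,
        batch_size=128,
        max_epochs=30,
        patience=5,
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_windows, tiny_split, small_config):
    return model.train(tiny_windows, tiny_split, small_config, protease="trypsin")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
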