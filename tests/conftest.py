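import numpy as np
import pytest

from phospsych import ModelSpec, TrainConfig, generate_dataset, train_model


@pytest.fixture(scope="session")
def small_dataset():
    """4 classes, 24 jittered training images each (shared across tests)."""
    return generate_dataset(n_classes=4, train_per_class=24, seed=7)


@pytest.fixture(scope="session")
def trained_cnn(small_dataset):
    """One shallow-CNN instance trained briefly on the small dataset."""
    spec = ModelSpec(arch="CNN_SHALLOW", n_classes=4, instance_seed=0)
    model, history = train_model(spec, small_dataset, TrainConfig(max_epochs=8))
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
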