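import numpy as np
import pytest
from hypothesis import settings

from healthgrid import classifier, synthetic_data

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def separable_dataset() -> classifier.LabeledDataset:
    """300 well-separated synthetic maps (100 per class), 240/60 split."""
    config = synthetic_data.GeneratorConfig(n_per_class=100, seed=42)
    return synthetic_data.generate_dataset(config)


@pytest.fixture(scope="session")
def trained_model(separable_dataset) -> classifier.CNNModel:
    model = classifier.build_model(classifier.CNNConfig(seed=42))
    classifier.train(model, separable_dataset)
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
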