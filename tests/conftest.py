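import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from poolattnet import (NetworkConfig, SyntheticSpec, TrainConfig,
                        build_network, generate_pressure_images,
                        split_train_val, train)

# a narrow variant used wherever training or repeated forwards are needed;
# 96x96 input keeps the final stage at 3x3, the pooling minimum
LIGHT_FILTERS = (8, 16, 32, 64)
LIGHT_SIZE = 96


def light_config(seed: int = 1, num_classes: int = 2) -> NetworkConfig:
    return NetworkConfig(filters=LIGHT_FILTERS, num_classes=num_classes,
                         input_size=(LIGHT_SIZE, LIGHT_SIZE, 3), seed=seed)


def run_light_training(seed: int, n_per_class: int = 32,
                       epochs: int = 30):
    """Generate synthetic data and train the narrow variant on it."""
    dataset = generate_pressure_images(
        SyntheticSpec(n_per_class=n_per_class, size=LIGHT_SIZE, seed=seed))
    train_set, val_set = split_train_val(dataset, 0.8, seed)
    model = build_network(light_config(seed))
    result = train(model, train_set, val_set,
                   TrainConfig(batch_size=16, epochs=epochs, seed=seed))
    return model, result, train_set, val_set


@pytest.fixture(scope="session")
def trained_light():
    """One scaled-down training run (seed 1), shared across the session."""
    return run_light_training(seed=1)


@pytest.fixture(scope="session")
def focal_test_images():
    """Held-out synthetic images with hotspot ground-truth masks."""
    dataset, masks = generate_pressure_images(
        SyntheticSpec(n_per_class=50, size=LIGHT_SIZE, seed=101),
        return_masks=True)
    return dataset, masks


@pytest.fixture
def rng():
    return np.random.default_rng(0)
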