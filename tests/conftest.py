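import numpy as np
import pytest

from crossdistill import (
    TrainingConfig,
    generate_synthetic_dual_modality,
    mnist_net_spec,
    train_supervised,
)


@pytest.fixture(scope="session")
def synthetic_train():
    """Small paired-modality training pool (16x16 to keep tests fast)."""
    return generate_synthetic_dual_modality(300, image_size=16, seed=42)


@pytest.fixture(scope="session")
def synthetic_test():
    return generate_synthetic_dual_modality(150, image_size=16, seed=43)


@pytest.fixture(scope="session")
def tiny_teacher(synthetic_train):
    """Original-modality teacher trained briefly on the small pool."""
    config = TrainingConfig(iterations=300, batch_size=64, learning_rate=0.05,
                            seed=7, eval_every=300)
    net, _ = train_supervised(
        mnist_net_spec(1, 16), synthetic_train.original, synthetic_train.labels,
        config, init_seed=7,
    )
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
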