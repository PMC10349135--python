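import numpy as np
import pytest

from epunet.pfm import extract_stacks
from epunet.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small balanced synthetic set (all cues) at desk scale."""
    return generate(SynthConfig(n_per_class=8, image_size=(16, 16), seed=11))


@pytest.fixture(scope="session")
def tiny_stacks(tiny_dataset):
    return extract_stacks(tiny_dataset.images)


@pytest.fixture(scope="session")
def tiny_model(tiny_stacks, tiny_dataset):
    """A briefly trained small ensemble shared by interpretation tests."""
    from epunet.model import TrainConfig, build_epu, train

    model = build_epu("base_i", input_size=(16, 16), seed=3)
    train(model, tiny_stacks, tiny_dataset.labels,
          TrainConfig(epochs=2, batch_size=8, seed=3))
    return model
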