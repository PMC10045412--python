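import numpy as np
import pytest

from gsnhv.blocks import StageSpec
from gsnhv.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest architecturally complete network layout."""
    return StageSpec(stage_channels=(8, 8, 16, 16), growth=4)


@pytest.fixture(scope="session")
def small_dataset():
    """Eight default-sized patches shared across read-only tests."""
    return generate_dataset(SynthConfig(n_images=8, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
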