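import numpy as np
import pytest

from latfuse import FusionConfig, PhantomSpec, RandomConvExtractor, make_structural_phantom


@pytest.fixture(scope="session")
def mock_extractor():
    return RandomConvExtractor(seed=0)


@pytest.fixture(scope="session")
def mock_cfg():
    return FusionConfig(feature_mode="mock")


@pytest.fixture
def phantom64():
    return make_structural_phantom(PhantomSpec(size=(64, 64), seed=11))


def structural(seed, size=64):
    return make_structural_phantom(PhantomSpec(size=(size, size), seed=seed))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
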