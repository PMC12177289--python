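import numpy as np
import pytest
from hypothesis import settings

from prairiesense import BandResponse, SceneConfig, simulate_scene

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def band():
    return BandResponse()


@pytest.fixture(scope="session")
def compact_bundle():
    """One down-scaled simulated overflight with default (noisy) sensors."""
    return simulate_scene(SceneConfig.compact(), seed=7)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free down-scaled overflight for exact round-trip checks."""
    return simulate_scene(SceneConfig.compact(), seed=7, noise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
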