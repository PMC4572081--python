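import numpy as np
import pytest

from tracenet.gabor import GaborParams, build_filter_bank
from tracenet.network import LayerSpec, NetworkProfile, NetworkState


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def bank():
    """Default quadrature Gabor bank (4 frequencies x 4 orientations)."""
    return build_filter_bank(GaborParams())


def make_mini_profile() -> NetworkProfile:
    """A very small hierarchy for fast unit tests (not a study condition)."""
    return NetworkProfile(
        name="scaled-32",  # reuse a registered name so checkpoints round-trip
        input_dims=(32, 32),
        gabor=GaborParams(),
        layers=(
            LayerSpec(12, 30, 3.0, 1.38, 1.5, 96.8, 190.0, 0.05, 0.0, "hebb"),
            LayerSpec(12, 30, 3.0, 2.7, 1.5, 92.0, 40.0, 0.03, 0.6, "trace"),
            LayerSpec(12, 30, 4.0, 4.0, 1.6, 88.0, 75.0, 0.005, 0.8, "trace"),
            LayerSpec(12, 30, 5.0, 6.0, 1.4, 95.0, 26.0, 0.005, 0.8, "trace"),
        ),
    )


@pytest.fixture(scope="session")
def mini_state():
    return NetworkState.initialize(make_mini_profile(), seed=0)
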