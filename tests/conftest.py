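import numpy as np
import pytest

from redtidenet.synthetic import SyntheticSceneParams, generate_benchmark, generate_scene


@pytest.fixture(scope="session")
def small_params() -> SyntheticSceneParams:
    return SyntheticSceneParams(height=64, width=64, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_params):
    return generate_scene(small_params)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 train + 1 test scenes of 96x96: small enough for training tests."""
    return generate_benchmark(
        n_train_scenes=2,
        n_test_scenes=1,
        params=SyntheticSceneParams(height=96, width=96),
        seed=5,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
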