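import numpy as np
import pytest

from campari import OpticalModel, PhotoconversionModel, SyntheticScene


@pytest.fixture(scope="session")
def small_scene() -> SyntheticScene:
    """A compact 20-cell scene reused across rendering/extraction tests."""
    return SyntheticScene.random(n_cells=20, shape=(12, 160, 160), seed=11)


@pytest.fixture(scope="session")
def noiseless_optics() -> OpticalModel:
    return OpticalModel(
        dark_green=5.0,
        dark_red=7.0,
        contamination_ratio=0.15,
        autofluor_intercept={"left": 3.0},
        shot_noise_scale=0.0,
        read_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def pc_model() -> PhotoconversionModel:
    return PhotoconversionModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
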