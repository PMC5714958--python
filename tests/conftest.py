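import numpy as np
import pytest

from valmux.config import EffectSpec, NoiseSpec, StudyConfig, box_roi


@pytest.fixture(scope="session")
def small_shape():
    return (8, 8, 8)


@pytest.fixture(scope="session")
def small_roi(small_shape):
    return box_roi(small_shape, (2, 2, 2), (5, 5, 5))


@pytest.fixture
def noiseless_config(small_shape, small_roi):
    return StudyConfig(
        n_subjects=1,
        grid_shape=small_shape,
        seed=11,
        noise=NoiseSpec(sigma=1.0, ar1_rho=0.0, smooth_fwhm_mm=0.0),
        effects=[
            EffectSpec("value_linear", small_roi, 0.1),
            EffectSpec("mean_offset", small_roi, 0.5),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
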