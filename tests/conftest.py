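import numpy as np
import pytest

from pgccscreen import fixtures as fx
from pgccscreen import models


@pytest.fixture(scope="session")
def noiseless_sar() -> fx.PlantedSAR:
    return fx.PlantedSAR.random(system="MACCS", n_nonzero=12, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_sar() -> fx.PlantedSAR:
    return fx.PlantedSAR.random(system="MACCS", n_nonzero=12, noise_sd=0.25, seed=0)


@pytest.fixture(scope="session")
def small_library(noisy_sar):
    """60-compound synthetic library used across modelling tests."""
    return fx.generate_compound_library(60, noisy_sar, seed=11)


@pytest.fixture(scope="session")
def fixture_image():
    """Canonical 12 non-PGCC / 3 PGCC / 2 dead well plus its truth."""
    img, truth = fx.generate_plate_image(12, 3, 2, seed=7)
    return img, truth


@pytest.fixture(scope="session")
def default_params():
    return fx.default_segmentation_params()


@pytest.fixture(scope="session")
def tiny_plan():
    return models.build_cv_plan(60, rounds=2, folds=10, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
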