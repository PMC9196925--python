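"""Shared fixtures: small synthetic scenes exercising the full pipeline."""

import numpy as np
import pytest

from maflim.core import AcquisitionConfig, RegionMasks
from maflim import simulate as sim
from maflim.preprocess import preprocess_image


@pytest.fixture(scope="session")
def config():
    """Desk-scale acquisition: 16x16 pixels, full 149-sample channels."""
    return AcquisitionConfig(rows=16, cols=16)


@pytest.fixture(scope="session")
def irf(config):
    return sim.default_irf(config)


@pytest.fixture(scope="session")
def noiseless_scene():
    return sim.SceneSpec(
        region1_params=sim.default_lesion_params(),
        region2_params=sim.default_surround_params(),
        noise_model=None,
        offset=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_image(noiseless_scene, config, irf):
    return sim.generate_lesion_image(noiseless_scene, config, irf)


@pytest.fixture(scope="session")
def processed_noiseless(noiseless_image):
    return preprocess_image(noiseless_image, seed=0)


@pytest.fixture(scope="session")
def noisy_image(config, irf):
    return sim.generate_lesion_image(sim.default_scene(seed=2), config, irf)


@pytest.fixture(scope="session")
def disc_masks(config):
    """Hand-built region masks from the generator's lesion geometry."""
    lesion = sim.disc_mask(config.rows, config.cols)
    valid = np.ones_like(lesion, dtype=bool)
    return RegionMasks(valid=valid, region1=lesion, region2=~lesion)


@pytest.fixture(scope="session")
def identical_scene():
    """Both regions share one parameter set: every global feature must be 0."""
    params = sim.default_surround_params()
    return sim.SceneSpec(
        region1_params=params,
        region2_params=params,
        noise_model=None,
        offset=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def identical_image(identical_scene, config, irf):
    return sim.generate_lesion_image(identical_scene, config, irf)
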