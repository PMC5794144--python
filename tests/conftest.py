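import dataclasses

import numpy as np
import pytest

from thermovine.geometry import CameraModel, TraverseSpec
from thermovine.synth import CampaignDesign, SynthParams
from thermovine.thermal import ReferenceTemperatures


@pytest.fixture
def camera():
    return CameraModel()


@pytest.fixture
def traverse():
    return TraverseSpec()


@pytest.fixture
def small_camera():
    """Low-resolution camera for cheap frame rendering."""
    return CameraModel(resolution=(32, 32))


@pytest.fixture
def small_design():
    return CampaignDesign(n_dates=2, n_blocks=2)


@pytest.fixture
def noiseless_params():
    return dataclasses.replace(SynthParams(), pixel_noise_sd=0.0)


@pytest.fixture
def refs():
    return ReferenceTemperatures(t_wet=20.0, t_dry=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
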