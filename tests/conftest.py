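import math

import numpy as np
import pytest

from pointloc import CameraModel, PriorConfig, RoiGeometry, sigma0

SIGMA0 = sigma0(639.0, 1.4)  # nm, default optics


@pytest.fixture
def cam() -> CameraModel:
    return CameraModel(gain=50.0, offset=100.0, readout_sd=10.0, pixel_size=80.0)


@pytest.fixture
def priors() -> PriorConfig:
    return PriorConfig(sigma0=SIGMA0, log_background_center=math.log(1.0))


@pytest.fixture
def roi9() -> RoiGeometry:
    return RoiGeometry(width=9, height=9, pixel_size=80.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210517)
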