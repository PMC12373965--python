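import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from transocular.optics import (
    DetectionConfig,
    EyeGeometry,
    IlluminationTrain,
)


@pytest.fixture
def adult_eye():
    return EyeGeometry()


@pytest.fixture
def detection_03():
    return DetectionConfig(na_detection=0.3)


@pytest.fixture
def clinical_train():
    """1:1 relay of the 1.8 mm LED through an 18 mm objective."""
    return IlluminationTrain()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
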