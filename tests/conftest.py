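import numpy as np
import pytest

from petirae.simulate import default_phantom_spec, make_phantom_pair
from petirae.volumes import ImageVolume, LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def noiseless_pair():
    """Deterministic noiseless phantom with the default liver lesion."""
    spec = default_phantom_spec(noise_sd=0.0)
    return make_phantom_pair(spec, seed=0)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), units="SUV"):
    return ImageVolume(
        data=np.asarray(data, dtype=float),
        spacing=spacing,
        origin=origin,
        modality="PET",
        units=units,
    )


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), label="m"):
    return LabelMask(
        data=np.asarray(data, dtype=np.uint8), spacing=spacing, origin=origin, label=label
    )
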