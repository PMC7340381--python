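import numpy as np
import pytest

from starletao import OpticalConfig, RasterImage, SpecimenSpec, make_specimen


@pytest.fixture(scope="session")
def config():
    """Default imaging system: 690 nm emission, NA 1.4, quarter-Airy pixels."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def filament_object(config):
    """400x400 filament specimen at the simulator's pixel pitch."""
    spec = SpecimenSpec(
        kind="filaments", shape=(400, 400), pixel_size=config.pixel_size, seed=11
    )
    return make_specimen(spec)


@pytest.fixture(scope="session")
def blob_object(config):
    """256x256 nucleus-like specimen (the sweep/demo object)."""
    spec = SpecimenSpec(
        kind="blobs", shape=(256, 256), pixel_size=config.pixel_size, seed=11, count=8
    )
    return make_specimen(spec)


@pytest.fixture()
def random_image():
    rng = np.random.default_rng(42)
    return RasterImage(pixels=rng.uniform(0, 100, size=(32, 32)), pixel_size=50.0)
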