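import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import apitv as av

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_geom():
    """8x8 grid, 4 views, 12 detector elements — small enough for the
    explicitly assembled sparse system matrix."""
    return av.ScanGeometry(
        sod=50.0, sdd=100.0, n_views=4, n_det=12, det_pitch=2.0,
        image_n=8, pixel_size=1.0,
    )


@pytest.fixture
def small_geom():
    """Half-scale variant of the reference geometry (128 image, 256 dets)."""
    return av.ScanGeometry(n_views=60, n_det=256, image_n=128)


@pytest.fixture(scope="session")
def truth128():
    return av.rasterize(av.shepp_logan_spec("high_contrast"), 128)


@pytest.fixture(scope="session")
def sino128(truth128):
    geom = av.ScanGeometry(n_views=60, n_det=256, image_n=128)
    return av.forward_project(truth128, geom)
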