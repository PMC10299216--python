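import numpy as np
import pytest

from radioresponse import (
    RadiobiologyParams,
    default_vf_table,
    init_grid_from_image,
    make_virtual_tumour,
)


@pytest.fixture
def params():
    return RadiobiologyParams()


@pytest.fixture
def vf_table():
    return default_vf_table()


@pytest.fixture
def small_tumour_image():
    """A ~1 cm spherical lesion: small enough for fast full-course runs."""
    return make_virtual_tumour(diameter=10.0, voxel_size=2.0, padding=1)


@pytest.fixture
def small_grid(small_tumour_image):
    return init_grid_from_image(small_tumour_image)


@pytest.fixture
def rng():
    return np.random.default_rng(20230620)
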