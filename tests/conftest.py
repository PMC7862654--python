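import numpy as np
import pytest

from ibt.simulate import (NoiseModel, PSFModel, six_point_fixture,
                          six_point_geometry, simulate_stack)
from ibt.stack import AcquisitionGeometry


@pytest.fixture
def geom_256():
    """The canonical cellular scan: 20 um field at 256 x 256 pixels."""
    return AcquisitionGeometry(scan_area_x_um=20.0, scan_area_y_um=20.0,
                               n_pixels_x=256, n_pixels_y=256,
                               beam_width_nm=100.0)


@pytest.fixture
def six_point_setup():
    """Six-molecule validation array: 50 nm pixels, 120 nm beam FWHM."""
    geom = six_point_geometry(n_pixels=64, pixel_nm=50.0, beam_width_nm=120.0)
    obj = six_point_fixture(geom)
    psf = PSFModel(lateral_fwhm_nm=120.0)
    return geom, obj, psf


@pytest.fixture
def noisy_six_point_stack(six_point_setup):
    geom, obj, psf = six_point_setup
    noise = NoiseModel(gamma_shape=3.0, extraction_efficiency=0.03, seed=11)
    return simulate_stack(obj, psf, noise, geom, n_slices=40)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
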