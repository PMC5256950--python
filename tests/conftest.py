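import numpy as np
import pytest

from nanoflim.flim import apply_filters, fit_image
from nanoflim.simulate import FlimSimParams, simulate_decay_cube


@pytest.fixture(scope="session")
def donor_cube():
    """Small donor-only decay cube at the reference lifetime (2402 ps)."""
    params = FlimSimParams(shape=(16, 16), f_interacting=0.0, seed=11)
    cube, gt = simulate_decay_cube(params)
    return cube, gt


@pytest.fixture(scope="session")
def donor_fits(donor_cube):
    """Per-pixel fits of the donor-only cube (shared: fitting is the slow part)."""
    cube, gt = donor_cube
    fits = fit_image(cube)
    return fits, gt


@pytest.fixture(scope="session")
def donor_image(donor_fits):
    fits, gt = donor_fits
    return apply_filters(fits), gt
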