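import numpy as np
import pytest

from cringdyn.focimetry import ImageStack
from cringdyn.synthgen import render_focus


@pytest.fixture
def rng():
    return np.random.default_rng(20150115)


def make_focus_stack(shape=(8, 32, 32), centers=((4.0, 16.0, 16.0),),
                     total_photons=5000.0, background=100.0, noise_rng=None,
                     sigma_lateral_px=1.0, sigma_axial_planes=2.0):
    """Small stack with rendered Gaussian foci, optional Poisson noise."""
    vox = np.full(shape, float(background))
    for c in centers:
        render_focus(vox, c, total_photons, sigma_lateral_px, sigma_axial_planes)
    if noise_rng is not None:
        vox = noise_rng.poisson(vox).astype(float)
    return ImageStack(voxels=vox, stack_id="test")
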