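import numpy as np
import pytest
from hypothesis import settings

from arborquant.images import PixelImage

settings.register_profile("no_db", database=None, deadline=None)
settings.load_profile("no_db")


@pytest.fixture
def grating():
    """Factory for noise-free parallel-line images at a known visual angle."""

    def make(theta_deg, n=160, period=10.0, px_size_um=0.5):
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        th = np.deg2rad(theta_deg)
        # perpendicular coordinate of a line at visual angle theta (y up)
        u = -np.sin(th) * xx + np.cos(th) * (-yy)
        return PixelImage(0.5 + 0.5 * np.cos(2 * np.pi * u / period), px_size_um)

    return make
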