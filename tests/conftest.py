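import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def render_stripes(theta_deg, shape=(48, 48), period=12.0):
    """Plane of parallel stripes whose ridges run along ``theta_deg``.

    Visual convention: angle counter-clockwise from +x with the pia up
    (y up), so intensity varies along the normal direction only.
    """
    t = np.deg2rad(theta_deg)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    phase = xx * np.sin(t) + yy * np.cos(t)
    return np.sin(2 * np.pi * phase / period)
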