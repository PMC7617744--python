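import numpy as np
import pytest

import roboulm as r


@pytest.fixture(scope="session")
def probe():
    return r.ProbeModel()


@pytest.fixture(scope="session")
def psf(probe):
    return r.default_psf(probe)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def speckle_volume(grid, seed, n_scatterers=250, probe=None, psf=None,
                   shift=(0.0, 0.0, 0.0), box_margin_mm=2.0):
    """Render a speckle volume from random point scatterers.

    The scatterer field extends ``box_margin_mm`` beyond the grid so that
    shifted renderings keep content flowing in at the borders.
    """
    probe = probe if probe is not None else r.ProbeModel()
    psf = psf if psf is not None else r.default_psf(probe)
    g = np.random.default_rng(seed)
    lo = grid.origin - box_margin_mm
    hi = grid.origin + grid.extent_mm + box_margin_mm
    pos = g.uniform(lo, hi, size=(n_scatterers, 3))
    amp = g.rayleigh(1.0, size=n_scatterers)
    from roboulm.imaging import _render_points

    data = _render_points(pos + np.asarray(shift, float), amp, probe, grid, psf)
    return r.Volume(data=data, grid=grid)
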