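import numpy as np
import pytest

from cortexhsi import phantom as ph
from cortexhsi import spectra as sp
from cortexhsi.imaging import DetectorConfig, Hypercube


@pytest.fixture(scope="session")
def spectra():
    return sp.load_spectra()


@pytest.fixture(scope="session")
def scattering():
    return sp.default_scattering_model()


@pytest.fixture(scope="session")
def default_phantom():
    """Paper-like synthetic phantom: one ~100 μm and one ~20 μm vessel."""
    return ph.make_default_phantom(seed=7)


@pytest.fixture(scope="session")
def homogeneous_phantom():
    """All-gray-matter slab (no vessels), standard 2.4×2.4×1 mm geometry."""
    labels = np.full((240, 240, 100), ph.GRAY_MATTER, dtype=np.uint8)
    return ph.CortexPhantom(labels, voxel_size=0.01)


def make_cube(wavelengths, intensity, pl_total=None, pl_vessel=None,
              pl_gray=None, n_pixels=(4, 4), condition=""):
    """Tiny synthetic hypercube with broadcastable per-wavelength maps."""
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    m = wl.size
    shape = (m,) + tuple(n_pixels)

    def _full(x, default):
        if x is None:
            x = default
        arr = np.broadcast_to(np.asarray(x, dtype=float), shape).copy()
        return arr

    inten = _full(intensity, 1.0)
    plt = _full(pl_total, 1.0)
    plv = _full(pl_vessel, 0.0)
    plg = plt - plv if pl_gray is None else _full(pl_gray, None)
    nd = np.where(np.isfinite(inten) & (inten > 0), 1, 0).astype(np.int64)
    det = DetectorConfig(fov_size=(1.2, 1.2), n_pixels=tuple(n_pixels))
    return Hypercube(wavelengths=wl, intensity=inten, pl_total=plt,
                     pl_vessel=plv, pl_gray=plg, n_detected=nd,
                     condition=condition, detector=det)
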