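"""Shared fixtures: one microscope and a few small rendered focal series.

Session-scoped so the rendering cost is paid once; every fixture is
deterministic (fixed seeds).
"""

import numpy as np
import pytest

import focalseries as fs


@pytest.fixture(scope="session")
def mp200():
    """200 kV microscope with C_s = 1.4 mm and 7% amplitude contrast."""
    return fs.MicroscopeParams(200.0, cs=1.4e7, amp_phase=0.07)


@pytest.fixture(scope="session")
def geom20():
    """20 images, 32 Å steps, 8000 Å underfocus (oscillation-rich)."""
    return fs.SeriesGeometry(20, 32.0, 8000.0)


@pytest.fixture(scope="session")
def amorphous_series(mp200, geom20):
    """Noiseless thin amorphous film, 128 px at 1 Å: broad Thon-ring signal."""
    spec = fs.make_amorphous(0.08, 128.0, 20.0, seed=1)
    return fs.render_focal_series(spec, mp200, geom20, n=128, pixel=1.0)


@pytest.fixture(scope="session")
def flat_amorphous_series(mp200, geom20):
    """Amorphous film with all atoms at z = 0 (single-plane weak-phase object)."""
    spec = fs.make_amorphous(0.08, 128.0, 1.0, seed=5)
    spec.z[:] = 0.0
    return spec, fs.render_focal_series(spec, mp200, geom20, n=128, pixel=1.0)


@pytest.fixture(scope="session")
def hex_series(mp200):
    """Graphene-oxide-like hexagonal lattice at z = 0, 1660 Å defocus."""
    geom = fs.SeriesGeometry(20, 32.0, 1660.0)
    spec = fs.make_hex_lattice(2.13, 128 * 0.7)
    series = fs.render_focal_series(spec, mp200, geom, n=128, pixel=0.7)
    return spec, series


@pytest.fixture(scope="session")
def truth_fit(geom20, mp200):
    """Known-truth aberrations of geom20 wrapped as a fit result."""
    return fs.CtfFitResult.from_geometry(geom20, mp200.cs)
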