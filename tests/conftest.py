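"""Shared fixtures: default optics, geometries and small bead phantoms.

Everything is generated programmatically; simulation sizes are kept small
(128–256 px fields) except where a test explicitly exercises the
full-scale experiment.
"""

import warnings

import numpy as np
import pytest

import ledscope as ls


@pytest.fixture(scope="session")
def optics() -> ls.OpticalSystem:
    return ls.OpticalSystem()


@pytest.fixture(scope="session")
def geom() -> ls.LEDArrayGeometry:
    """DPC-study geometry (16x24, 4.7 mm pitch, 100 mm)."""
    return ls.dpc_geometry()


@pytest.fixture(scope="session")
def geom110() -> ls.LEDArrayGeometry:
    """Darkfield geometry (same array at 110 mm)."""
    return ls.LEDArrayGeometry()


@pytest.fixture(scope="session")
def pixel_size(optics) -> float:
    return optics.magnified_pixel_size_um


@pytest.fixture(scope="session")
def small_phantom(pixel_size) -> ls.BeadPhantom:
    """Three 5 µm beads in a 256² field (150x150 µm)."""
    return ls.random_bead_phantom(n_beads=3, radius_um=5.0, field_size=(256, 256),
                                  pixel_size_um=pixel_size, seed=1)


@pytest.fixture(scope="session")
def small_specimen(small_phantom, optics) -> ls.SpecimenField:
    return ls.bead_opl_map(small_phantom, wavelength_um=optics.wavelength_um)


@pytest.fixture(scope="session")
def weak_phantom(pixel_size) -> ls.BeadPhantom:
    """Single centered bead with peak phase ~0.2 rad (weak-object regime)."""
    n = 256
    c = n * pixel_size / 2
    return ls.BeadPhantom(((c, c, 5.0),), n_bead=1.562, n_medium=1.56,
                          field_size=(n, n), pixel_size_um=pixel_size)


@pytest.fixture(scope="session")
def weak_specimen(weak_phantom) -> ls.SpecimenField:
    return ls.bead_opl_map(weak_phantom)


@pytest.fixture(autouse=True)
def _quiet_pattern_clip_warnings():
    """Clipped whole-grid patterns (radius 14) are routine in the sweeps."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*pattern clipped to the grid.*")
        yield
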