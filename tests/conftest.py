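import numpy as np
import pytest

from blinktrack.geometry import DetectorGeometry, bragg_two_theta, ring_mask
from blinktrack.simulate import BeamModel

GOLD_A = 4.0782
CU_KALPHA_KEV = 8.0478


@pytest.fixture
def toy_geom():
    """Small wide-angle detector used by the fast simulation tests."""
    return DetectorGeometry(
        energy_kev=CU_KALPHA_KEV,
        distance_mm=5.0,
        pixel_pitch_mm=1.0,
        beam_center=(16.0, 16.0),
        n_rows=32,
        n_cols=32,
    )


@pytest.fixture
def au111_ring(toy_geom):
    tt = bragg_two_theta(toy_geom.wavelength, GOLD_A, (1, 1, 1))
    return ring_mask(toy_geom, tt, 0.8, hkl=(1, 1, 1))


@pytest.fixture
def mono_beam():
    return BeamModel(mode="monochromatic", rocking_width=0.3)


@pytest.fixture
def dxt_geom():
    """Beamline-like geometry: 15.8 keV pink beam, 50 mm distance."""
    return DetectorGeometry(
        energy_kev=15.8,
        distance_mm=50.0,
        pixel_pitch_mm=0.25,
        beam_center=(80.0, 80.0),
        n_rows=160,
        n_cols=160,
        bandwidth=0.1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
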