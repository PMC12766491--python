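import math

import numpy as np
import pytest

from icsxrd.crystal import AtomSite, CrystalStructure, UnitCell
from icsxrd.detector_sim import AcquisitionConfig, DetectorGeometry
from icsxrd.powder import Pattern1D


@pytest.fixture
def toy_cubic() -> CrystalStructure:
    """One carbon atom in a 4 A cubic cell: the simplest diffracting crystal."""
    return CrystalStructure("toy", UnitCell(4.0, 4.0, 4.0), [AtomSite("C", (0.0, 0.0, 0.0))])


@pytest.fixture
def three_atom_cell() -> CrystalStructure:
    """Fixed pseudo-random 3-atom triclinic cell for structure-factor checks."""
    rng = np.random.default_rng(42)
    cell = UnitCell(5.2, 6.1, 7.3, 95.0, 101.0, 88.0)
    sites = [
        AtomSite("C", tuple(rng.uniform(0, 1, 3)), 1.0, 0.5),
        AtomSite("O", tuple(rng.uniform(0, 1, 3)), 0.8, 1.0),
        AtomSite("Ca", tuple(rng.uniform(0, 1, 3)), 1.0, 0.0),
    ]
    return CrystalStructure("random3", cell, sites)


@pytest.fixture
def small_geometry() -> DetectorGeometry:
    """Down-scaled detector so image tests stay fast; keeps pitch and distance."""
    return DetectorGeometry(
        shape=(180, 160),
        pixel_pitch_um=172.0,
        distance_mm=100.0,
        beam_center=(92.3, 78.7),
        gap_rows=(86, 94),
    )


@pytest.fixture
def ring_pattern() -> Pattern1D:
    """Smooth pattern with three well-separated Gaussian rings on a baseline."""
    tt = np.arange(0.0, 18.0, 0.01)
    y = 0.05 * np.ones_like(tt)
    for c, a, w in [(4.6, 1.0, 0.3), (7.5, 0.7, 0.3), (11.7, 0.4, 0.35)]:
        y += a * np.exp(-0.5 * ((tt - c) / w) ** 2)
    return Pattern1D(tt, y)


@pytest.fixture
def fast_acq() -> AcquisitionConfig:
    return AcquisitionConfig(exposure_s=1.0, n_frames=20, seed=123)
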