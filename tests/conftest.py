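"""Shared fixtures: one medium-sized simulated datacube reused across tests."""

import numpy as np
import pytest

from tcbfstem.optics import AberrationSurface, OpticalConfig
from tcbfstem.phantom_sim import SimConfig, make_phantom, simulate_datacube


@pytest.fixture(scope="session")
def small_cube():
    """Noise-free 16x16-scan cube at 1-um defocus, band-limited phantom."""
    # parallax spread alpha*defocus = 24 A (~3 scan px), well inside the
    # 128-A scan field so registration is not wraparound-limited
    cfg = OpticalConfig(voltage_kv=300.0, alpha=4.0e-3)
    ab = AberrationSurface(defocus=6000.0)
    obj = make_phantom("gold_on_carbon", 320, 1.0,
                       params={"lattice_amp": 0.0, "disk_radius": (12, 30)},
                       seed=11)
    sim = SimConfig(optics=cfg, aberrations=ab, scan_shape=(16, 16),
                    scan_step=8.0, detector_shape=(32, 32), dose=None, seed=4)
    return simulate_datacube(obj, sim)


@pytest.fixture(scope="session")
def small_cube_truth():
    return {"defocus": 6000.0, "alpha": 4.0e-3, "scan_step": 8.0}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
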