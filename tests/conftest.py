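import numpy as np
import pytest

from hepaflow import DensitometryCalibration, OpticalGeometry
from hepaflow.synth import ClearanceScenario, SpeckleScenario, simulate_clearance


@pytest.fixture
def cal() -> DensitometryCalibration:
    """ICG-like calibration: absorbance ~0.6 at 3 mg/L over a 1 cm path."""
    return DensitometryCalibration(epsilon=0.2, path_z=1.0, u0=1.0, delta_u=1e-3)


@pytest.fixture
def geom() -> OpticalGeometry:
    """Bench geometry with macroscopic values (hand-checkable coefficient)."""
    return OpticalGeometry(wavelength_nm=650.0, distance_l_cm=7.5, beam_waist_mm=0.5, sigma=1.0)


@pytest.fixture
def sim_geom() -> OpticalGeometry:
    """Effective backscatter geometry used by the simulator defaults."""
    return OpticalGeometry.effective_backscatter()


@pytest.fixture
def noiseless_trace(cal):
    scen = ClearanceScenario(noise_rel=0.0)
    trace, truth = simulate_clearance(scen, cal)
    return trace, truth


@pytest.fixture
def fast_speckle_scenario(sim_geom) -> SpeckleScenario:
    """Down-scaled speckle scenario for unit tests: short records, few replicates."""
    return SpeckleScenario(
        velocity_true=1.0,
        geometry=sim_geom,
        sampling_rate=2.0e6,
        duration=0.02,
        snr=np.inf,
        n_replicates=2,
        seed=11,
    )
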