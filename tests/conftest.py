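import numpy as np
import pytest

from xpct import optics, simulate


@pytest.fixture(scope="session")
def nd_table() -> optics.ScatteringTable:
    return optics.bundled_table("Nd")


@pytest.fixture(scope="session")
def u_table() -> optics.ScatteringTable:
    return optics.bundled_table("U")


@pytest.fixture(scope="session")
def small_phantom() -> simulate.PhantomVolume:
    """Compact layered eye-like phantom for pipeline tests."""
    return simulate.default_retina_phantom(shape=(8, 128, 128))


@pytest.fixture(scope="session")
def small_geometry() -> simulate.AcquisitionGeometry:
    return simulate.AcquisitionGeometry.over_360(16.0, 650.0, 149.0, 180)


@pytest.fixture(scope="session")
def small_stack(small_phantom, small_geometry) -> simulate.HologramStack:
    det = simulate.DetectorParams(n_flats=3, n_darks=3)
    return simulate.simulate_scan(small_phantom, small_geometry, det, seed=11)


def weak_phase_projection(shape=(32, 256, 256), max_phase=0.05):
    """Projected phase/OD of the default phantom, rescaled to the weak
    (linearizable) regime; returns (phase, od) single-angle 2D maps."""
    ph = simulate.default_retina_phantom(shape=shape)
    phase, od = simulate.project_stack(ph, np.array([0.0]))
    scale = max_phase / phase.max()
    return phase[0] * scale, od[0] * scale
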