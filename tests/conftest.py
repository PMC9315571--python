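import numpy as np
import pytest

from sonispec.hsio import ROI, SpectralCube
from sonispec.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_cube(rng):
    """Small random cube on the standard 18-channel 640-810 nm grid."""
    return SpectralCube(
        intensities=rng.uniform(0.0, 50.0, size=(5, 5, 18)),
        wavelengths_nm=np.arange(640.0, 811.0, 10.0),
        name="random",
    )


@pytest.fixture
def sloped_cube(rng):
    """Random cube plus a rising spectral ramp, so any background ROI has a
    positive target value (a valid ratio denominator)."""
    data = rng.uniform(0.0, 50.0, size=(5, 5, 18)) + np.linspace(0.0, 200.0, 18)
    return SpectralCube(intensities=data,
                        wavelengths_nm=np.arange(640.0, 811.0, 10.0),
                        name="sloped")


@pytest.fixture(scope="session")
def default_phantom():
    """One seeded default phantom shared across tests (read-only)."""
    cube, truth, rois = generate_phantom(PhantomConfig(seed=0))
    return cube, truth, {r.name: r for r in rois}


@pytest.fixture
def rect_roi():
    return ROI(name="r", kind="rect", params=(1, 1, 4, 4), role="probe")
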