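import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tdavine import Series, TimePointCloud

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def lattice(nx=3, ny=3, nz=1):
    return np.mgrid[0:nx, 0:ny, 0:nz].reshape(3, -1).T.astype(float)


@pytest.fixture
def small_series():
    """3 timepoints on a 3x3x1 lattice with varying amplitudes."""
    coords = lattice()
    rng = np.random.default_rng(42)
    clouds = tuple(
        TimePointCloud(t, coords, rng.uniform(100.0, 200.0, len(coords)))
        for t in range(3)
    )
    return Series(clouds)


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
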