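import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vocalfem.geometry import ChannelProfile, build_m5_mesh
from vocalfem.solid_fem import MaterialParams

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_mesh():
    """~300-element mesh used by most solid/coupled tests."""
    return build_m5_mesh(0.75)


@pytest.fixture(scope="session")
def medium_mesh():
    """~1000-element mesh for dynamics-sensitive checks."""
    return build_m5_mesh(0.4)


@pytest.fixture
def nominal_material():
    return MaterialParams()


def channel_from_gaps(gaps, z_in=-3.6, z_out=0.0, depth=14.0):
    """Build a ChannelProfile directly from a gap profile (test helper)."""
    gaps = np.asarray(gaps, dtype=float)
    n = gaps.size
    z = np.linspace(z_in, z_out, n)
    i_min = int(n - 1 - np.argmin(gaps[::-1]))
    return ChannelProfile(z=z, gap=gaps, area=gaps * depth,
                          perimeter=np.full(n, 2.0 * depth), depth=depth,
                          i_min=i_min, contact_plane_x=8.4)


@pytest.fixture
def make_channel():
    return channel_from_gaps
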