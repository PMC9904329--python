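import numpy as np
import pytest

from hiddenum import geometry
from hiddenum.bayes import UrnSpec


@pytest.fixture(scope="session")
def board():
    return geometry.make_board()


@pytest.fixture(scope="session")
def vertical_bars():
    return geometry.make_bar_occluder("vertical")


@pytest.fixture(scope="session")
def horizontal_bars():
    return geometry.make_bar_occluder("horizontal")


@pytest.fixture(scope="session")
def small_mesh():
    return geometry.make_mesh_occluder(40, 60)


@pytest.fixture(scope="session")
def published_urns():
    """Urns matching the printed hidden/visible area ratios of the two
    mesh occluders (0.27 and 1.05) on the 117-cell board."""
    small = geometry.OcclusionGeometry.from_ratio(0.27)
    large = geometry.OcclusionGeometry.from_ratio(1.05)
    return {"mesh_40_60": UrnSpec(small.N_v, small.N_h),
            "mesh_30_45": UrnSpec(large.N_v, large.N_h)}


@pytest.fixture(scope="session")
def exp1_levels():
    return np.array([-8, -6, -4, -2, -1, 0, 1, 2, 4, 6, 8], dtype=float)
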