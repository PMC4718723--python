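import numpy as np
import pytest

from helixtrace import synthetic_data as sd
from helixtrace.helix_geometry import build_ideal_helix


@pytest.fixture(scope="session")
def helix30():
    return build_ideal_helix(30)


@pytest.fixture(scope="session")
def helix36():
    return build_ideal_helix(36)


@pytest.fixture(scope="session")
def small_bundle():
    """Well-separated four-helix bundle (no density contact between tubes)."""
    return sd.make_bundle(4, [20] * 4, spacing=12.0, rng_seed=11)


@pytest.fixture(scope="session")
def bundle_map(small_bundle):
    return sd.render_map(small_bundle.model, sd.MapSpec(), rng_seed=0)


def random_rigid(rng):
    """A random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans
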