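import warnings

import numpy as np
import pytest

from admdpath.synthetic import make_bba5_mimic, MimicSpec

# align_vectors warns on near-degenerate selections (e.g. 3-point triads);
# harmless here and noisy in bulk runs.
warnings.filterwarnings(
    "ignore", message="Optimal rotation is not uniquely or poorly defined")


@pytest.fixture(scope="session")
def mimic():
    """The 23-bead ββα mimic (native + extended endpoints + Gō potential)."""
    return make_bba5_mimic(MimicSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t
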