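import numpy as np
import pytest

from fenmor.synthetic import ToyComplexSpec, make_toy_complex, simulate_mode_trajectory


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex()


@pytest.fixture(scope="session")
def small_traj():
    """500-frame two-mode trajectory with ground truth, default conditions."""
    return simulate_mode_trajectory(ToyComplexSpec(n_frames=500, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng):
    """A random proper rotation + translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-20, 20, 3)
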