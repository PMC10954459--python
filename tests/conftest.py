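import numpy as np
import pytest

import helixbend as hb


@pytest.fixture(scope="session")
def ideal_b():
    return hb.make_ideal_helix(hb.B_FORM, 20)


@pytest.fixture(scope="session")
def ideal_a():
    return hb.make_ideal_helix(hb.A_FORM, 20)


@pytest.fixture(scope="session")
def quiet_config():
    """Generator config without ions or structural noise couplings."""
    return hb.GeneratorConfig(
        seed=123, n_frames=2000, n_bp=20, form_name="B", true_P_nm=48.0,
        bulk_mM=0.0, ext_occupancy=0.0, major_occupancy=0.0, minor_occupancy=0.0,
    )


@pytest.fixture(scope="session")
def quiet_trajectory(quiet_config):
    return hb.sample_trajectory(quiet_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240207)


def random_rotation(rng):
    """Haar-ish random rotation matrix from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
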