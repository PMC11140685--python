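import numpy as np
import pytest

from cortnet import synthetic as syn


@pytest.fixture(scope="session")
def ico_mesh():
    """Icosphere at subdivision 2 (162 vertices): the standard small cortex."""
    return syn.generate_mesh("icosphere", 2)


@pytest.fixture(scope="session")
def labeling(ico_mesh):
    """Default 68-parcel, 8-network labeling of the small cortex."""
    return syn.generate_parcellation(ico_mesh, 68, 8, seed=0)


@pytest.fixture(scope="session")
def grid_mesh():
    return syn.generate_mesh("flat_grid", 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ar1(phi: float, n: int, rng: np.random.Generator, burn: int = 100) -> np.ndarray:
    """Reference AR(1) series for oracle comparisons."""
    from scipy.signal import lfilter

    e = rng.standard_normal(n + burn)
    return lfilter([1.0], [1.0, -phi], e)[burn:]
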