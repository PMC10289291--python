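import numpy as np
import pytest

from lsmunet.ioprep import preprocess
from lsmunet.network import NetworkConfig, build_lsmu_net
from lsmunet.phantom import PhantomParams, generate_phantom

SMALL_GRID = (8, 64, 64)
SMALL_SPACING = (5.0, 5.6, 5.6)  # 64x64 covers the same field of view


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    return PhantomParams(
        grid_size=SMALL_GRID, spacing_mm=SMALL_SPACING, n_true_slices=6, seed=3
    )


@pytest.fixture(scope="session")
def small_case(small_params):
    """One generated phantom: (slab, labels, meta)."""
    return generate_phantom(small_params)


@pytest.fixture(scope="session")
def preprocessed_case(small_case):
    slab, labels, meta = small_case
    pslab, plab = preprocess(slab, labels)
    return pslab, plab, meta


@pytest.fixture(scope="session")
def tiny_model():
    """Width-factor-8 model on 32x32 grids: fast enough for unit tests."""
    cfg = NetworkConfig.scaled(8, in_plane_size=(32, 32), seed=0)
    return build_lsmu_net(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
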