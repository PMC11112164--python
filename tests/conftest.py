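import numpy as np
import pytest

from scutoid3d import phantoms
from scutoid3d.volume_io import LabelVolume, RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def wide_band_config():
    """Config whose band covers any phantom entirely."""
    return RunConfig(band_depth=1000.0)


@pytest.fixture(scope="session")
def quartet():
    return phantoms.make_scutoid_quartet(0.5)


@pytest.fixture(scope="session")
def prism_3x3():
    return phantoms.make_prism_lattice(3, 3)


@pytest.fixture(scope="session")
def small_shell():
    """~100-cell spheroidal patch phantom shared across tests."""
    spec = phantoms.default_phantom_spec(n_cells=100, rng_seed=11)
    volume, seeds = phantoms.make_voronoi_epithelium(spec)
    return spec, volume, seeds


def make_cuboid(shape=(12, 10, 8), label=1, spacing=(1.0, 1.0, 1.0), pad=1):
    vox = np.zeros(tuple(s + 2 * pad for s in shape), dtype=np.int64)
    vox[pad:-pad, pad:-pad, pad:-pad] = label
    return LabelVolume(vox, spacing)
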