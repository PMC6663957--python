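import numpy as np
import pytest

from blockpet.geometry import (ScannerSpec, demo_block_scanner,
                               demo_ring_scanner)
from blockpet.projection_data import ProjDataInfo
from blockpet.projectors import VoxelImage


@pytest.fixture(scope="session")
def mini_spec() -> ScannerSpec:
    """8 detectors/ring, 2 rings; small enough for exhaustive enumeration."""
    return ScannerSpec(
        name="mini", inner_radius=20.0, n_sides=8, n_blocks_transaxial=8,
        n_blocks_axial=2, n_crystals_per_block_transaxial=1,
        n_crystals_per_block_axial=1, crystal_size=(2.0, 2.0, 10.0),
        crystal_gap_transaxial=0.2, crystal_gap_axial=0.2,
        block_gap_transaxial=0.2, block_gap_axial=0.2)


@pytest.fixture(scope="session")
def mini_info(mini_spec) -> ProjDataInfo:
    return ProjDataInfo(mini_spec, num_tangential=7)


@pytest.fixture(scope="session")
def block_spec() -> ScannerSpec:
    return demo_block_scanner()


@pytest.fixture(scope="session")
def block_info(block_spec) -> ProjDataInfo:
    return ProjDataInfo(block_spec)


@pytest.fixture(scope="session")
def small_block_info() -> ProjDataInfo:
    """Dodecagon scanner reduced to one axial block: 8 rings, 192 crystals."""
    return ProjDataInfo(demo_block_scanner().with_axial_blocks(1),
                        num_tangential=60)


@pytest.fixture(scope="session")
def ring_spec() -> ScannerSpec:
    return demo_ring_scanner()


@pytest.fixture()
def small_grid() -> VoxelImage:
    return VoxelImage.zeros((21, 21, 5), (1.5, 1.5, 2.0))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20190729)
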