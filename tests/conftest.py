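import numpy as np
import pytest

from divplane.division3d import Partition
from divplane.shapes import Calibration, CellMask, digitize_shape


@pytest.fixture(scope="session")
def unit_cal() -> Calibration:
    return Calibration.cubic(1.0)


@pytest.fixture(scope="session")
def paper_cal() -> Calibration:
    """The resampled acquisition calibration: cubic 0.35 um voxels."""
    return Calibration.cubic(0.35)


@pytest.fixture(scope="session")
def ball10(unit_cal) -> CellMask:
    return digitize_shape("sphere", 10.0, unit_cal)


@pytest.fixture(scope="session")
def cube6(unit_cal) -> CellMask:
    """Solid 6^3 lattice with a 2-voxel margin."""
    occ = np.zeros((10, 10, 10), dtype=bool)
    occ[2:8, 2:8, 2:8] = True
    return CellMask(occ, unit_cal)


def random_partition(mask: CellMask, seed: int) -> Partition:
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, 3, size=mask.n_sites).astype(np.int8)
    if labels.min() == labels.max():  # ensure both daughters exist
        labels[0] = 3 - labels[0]
    return Partition(mask, labels)


def flat_split_partition(mask: CellMask, axis: int = 2, frac: float = 0.5) -> Partition:
    """Deterministic partition by a flat grid-aligned plane."""
    idx = np.argwhere(mask.occupancy)
    cut = np.quantile(idx[:, axis], frac)
    labels = np.where(idx[:, axis] <= cut, 1, 2).astype(np.int8)
    return Partition(mask, labels)
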