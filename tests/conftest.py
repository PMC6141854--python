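import numpy as np
import pandas as pd
import pytest

from lesionload import (
    Atlas,
    CohortTable,
    LesionMask,
    PatientRecord,
    VolumeGrid,
)


@pytest.fixture
def grid():
    return VolumeGrid((6, 6, 3), (2.0, 2.0, 2.0))


@pytest.fixture
def toy_atlas(grid):
    """Three-region toy parcellation: 1 white block, 2 gray blocks, rest background."""
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[:3, :3, :] = 1  # 27 voxels
    labels[3:, :3, :] = 2  # 27 voxels
    labels[:3, 3:, :] = 3  # 27 voxels
    regions = pd.DataFrame(
        {
            "region_id": [1, 2, 3],
            "name": ["white_block", "gray_block_a", "gray_block_b"],
            "tissue_class": ["white", "gray", "gray"],
        }
    )
    return Atlas(labels=labels, grid=grid, regions=regions)


@pytest.fixture
def small_cohort():
    return CohortTable(
        [
            PatientRecord("p1", "0", 30, 5),
            PatientRecord("p2", "2a", 18, 3),
            PatientRecord("p3", "2b", 8, 1),
            PatientRecord("p4", "3", 2, 0),
        ]
    )


def make_mask(grid, voxels, patient_id="p1", kind="followup_segmentation"):
    data = np.zeros(grid.shape, dtype=bool)
    for v in voxels:
        data[v] = True
    return LesionMask(data=data, grid=grid, patient_id=patient_id, kind=kind)


@pytest.fixture
def mask_factory():
    return make_mask
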