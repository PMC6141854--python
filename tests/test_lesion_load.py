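"""Regional lesion loads against a brute-force voxel-count oracle."""

import numpy as np
import pandas as pd
import pytest

from lesionload import (
    Atlas,
    CohortTable,
    PatientRecord,
    VolumeGrid,
    compute_load_matrix,
    region_load,
    total_volume,
)
from lesionload.lesion_load import LoadMatrix


def brute_force_load(mask, atlas, region_id):
    """Independent triple-loop voxel count of the load percentage."""
    nx, ny, nz = atlas.grid.shape
    region = overlap = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if atlas.labels[i, j, k] == region_id:
                    region += 1
                    if mask.data[i, j, k]:
                        overlap += 1
    return 100.0 * overlap / region


class TestRegionLoad:
    def test_quarter_overlap(self, grid, mask_factory):
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[:4, :5, :2] = 1  # 40 voxels
        atlas = Atlas(
            labels=labels,
            grid=grid,
            regions=pd.DataFrame({"region_id": [1], "name": ["a"], "tissue_class": ["gray"]}),
        )
        mask = mask_factory(grid, [(i, j, 0) for i in range(2) for j in range(5)])  # 10 inside
        assert region_load(mask, atlas, 1) == pytest.approx(25.0)

    def test_empty_lesion_and_full_coverage(self, toy_atlas, grid, mask_factory):
        empty = mask_factory(grid, [])
        assert all(region_load(empty, toy_atlas, rid) == 0.0 for rid in (1, 2, 3))
        full = mask_factory(grid, list(np.ndindex(grid.shape)))
        assert region_load(full, toy_atlas, 2) == pytest.approx(100.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            shape = tuple(rng.integers(3, 9, 3))
            grid = VolumeGrid(shape, (2.0, 2.0, 2.0))
            labels = rng.integers(0, 4, shape).astype(np.int32)
            while not labels.any():
                labels = rng.integers(0, 4, shape).astype(np.int32)
            present = sorted(set(labels.reshape(-1).tolist()) - {0})
            atlas = Atlas(
                labels=labels,
                grid=grid,
                regions=pd.DataFrame(
                    {
                        "region_id": present,
                        "name": [f"r{i}" for i in present],
                        "tissue_class": ["gray"] * len(present),
                    }
                ),
            )
            from tests.conftest import make_mask

            mask_data = rng.random(shape) < 0.3
            mask = make_mask(grid, list(zip(*np.nonzero(mask_data))))
            for rid in present:
                assert region_load(mask, atlas, rid) == brute_force_load(mask, atlas, rid)

    def test_conservation_of_lesion_voxels(self, toy_atlas, grid):
        rng = np.random.default_rng(3)
        from tests.conftest import make_mask

        mask_data = rng.random(grid.shape) < 0.4
        mask = make_mask(grid, list(zip(*np.nonzero(mask_data))))
        recovered = sum(
            region_load(mask, toy_atlas, rid) / 100.0 * toy_atlas.region_voxel_count(rid)
            for rid in (1, 2, 3)
        )
        on_labeled = int(np.count_nonzero(mask.data & (toy_atlas.labels > 0)))
        assert recovered == pytest.approx(on_labeled)
        assert on_labeled <= mask.n_voxels

    def test_monotone_under_mask_growth(self, toy_atlas, grid, mask_factory):
        small = mask_factory(grid, [(0, 0, 0)])
        big = mask_factory(grid, [(0, 0, 0), (1, 1, 1), (4, 1, 2)])
        for rid in (1, 2, 3):
            assert region_load(big, toy_atlas, rid) >= region_load(small, toy_atlas, rid)
        assert total_volume(big) >= total_volume(small)


class TestTotalVolume:
    def test_volume_in_ml(self, mask_factory):
        grid = VolumeGrid((10, 10, 10), (2.0, 2.0, 2.0))
        mask = mask_factory(grid, list(np.ndindex((10, 10, 10))))
        assert total_volume(mask) == pytest.approx(8.0)  # 1000 voxels x 8 mm^3

    def test_empty_and_unit_voxels(self, mask_factory):
        grid = VolumeGrid((3, 3, 3), (1.0, 1.0, 1.0))
        assert total_volume(mask_factory(grid, [])) == 0.0
        assert total_volume(mask_factory(grid, [(0, 0, 0), (1, 1, 1), (2, 2, 2)])) == pytest.approx(0.003)


class TestLoadMatrix:
    def test_matrix_shape_and_alignment(self, toy_atlas, grid, small_cohort, mask_factory):
        masks = [mask_factory(grid, [(0, 0, 0)], pid) for pid in small_cohort.patient_ids]
        lm = compute_load_matrix(masks, toy_atlas, small_cohort)
        assert lm.values.shape == (4, 3)
        assert lm.row_ids == small_cohort.patient_ids
        assert lm.column_ids == [1, 2, 3]

    def test_single_voxel_lesion_loads_one_region(self, toy_atlas, grid, small_cohort, mask_factory):
        masks = [mask_factory(grid, [(4, 1, 1)], pid) for pid in small_cohort.patient_ids]  # region 2
        lm = compute_load_matrix(masks, toy_atlas, small_cohort)
        nonzero_cols = np.nonzero(lm.values.sum(axis=0))[0]
        assert list(nonzero_cols) == [1]  # column of region 2
        assert lm.values[0, 1] == pytest.approx(100.0 / 27.0)

    def test_all_empty_masks(self, toy_atlas, grid, small_cohort, mask_factory):
        masks = [mask_factory(grid, [], pid) for pid in small_cohort.patient_ids]
        lm = compute_load_matrix(masks, toy_atlas, small_cohort)
        assert not lm.values.any() and not lm.total_volume_ml.any()

    def test_missing_mask_names_patient(self, toy_atlas, grid, small_cohort, mask_factory):
        masks = [mask_factory(grid, [], pid) for pid in small_cohort.patient_ids[:-1]]
        with pytest.raises(ValueError, match="p4"):
            compute_load_matrix(masks, toy_atlas, small_cohort)

    def test_mixed_kinds_rejected(self, toy_atlas, grid, small_cohort, mask_factory):
        masks = [mask_factory(grid, [], pid) for pid in small_cohort.patient_ids]
        masks[0] = mask_factory(grid, [], "p1", kind="adc_core")
        with pytest.raises(ValueError, match="mixed"):
            compute_load_matrix(masks, toy_atlas, small_cohort)

    def test_unlabeled_lesion_voxels_counted(self, toy_atlas, grid, small_cohort, mask_factory):
        # voxel (5,5,2) is background in the toy atlas
        masks = [mask_factory(grid, [(5, 5, 2)], pid) for pid in small_cohort.patient_ids]
        lm = compute_load_matrix(masks, toy_atlas, small_cohort)
        assert not lm.values.any()
        assert lm.unlabeled_voxels.tolist() == [1, 1, 1, 1]
        assert lm.total_volume_ml[0] == pytest.approx(0.008)

    def test_feature_accessor_and_tsv(self, toy_atlas, grid, small_cohort, mask_factory, tmp_path):
        masks = [mask_factory(grid, [(0, 0, 0)], pid) for pid in small_cohort.patient_ids]
        lm = compute_load_matrix(masks, toy_atlas, small_cohort)
        assert lm.feature("total_volume") is lm.total_volume_ml
        assert lm.feature(1)[0] > 0
        lm.to_tsv(tmp_path / "loads.tsv", toy_atlas)
        df = pd.read_csv(tmp_path / "loads.tsv", sep="\t")
        assert list(df.columns) == ["patient_id", "white_block", "gray_block_a", "gray_block_b", "total_volume_ml"]
        assert len(df) == 4

    def test_entries_validated(self):
        with pytest.raises(ValueError):
            LoadMatrix(
                values=np.array([[150.0]]),
                total_volume_ml=np.array([1.0]),
                row_ids=["p1"],
                column_ids=[1],
                delineation_kind="followup_segmentation",
            )
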