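"""Regional lesion loads: percentage of each atlas region covered by a lesion.

A patient's feature vector is one load per atlas region (121 for the default
29 white-matter + 92 gray-matter parcellation) plus the total lesion volume
in ml.  Lesion voxels falling on unlabeled (background) voxels count toward
the total volume but toward no regional load; their count is tracked per
patient so signal lost outside the parcellation stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Atlas, CohortTable, LesionMask


@dataclass
class LoadMatrix:
    """Patients x regions lesion-load percentages plus total volumes.

    ``values[i, j]`` is the percentage (0-100) of region ``column_ids[j]``
    covered by patient ``row_ids[i]``'s lesion; ``total_volume_ml[i]`` the
    patient's lesion volume in ml; ``unlabeled_voxels[i]`` the lesion voxels
    outside the parcellation.
    """

    values: np.ndarray
    total_volume_ml: np.ndarray
    row_ids: list[str]
    column_ids: list[int]
    delineation_kind: str
    unlabeled_voxels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.total_volume_ml = np.asarray(self.total_volume_ml, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.column_ids)):
            raise ValueError("load matrix shape does not match row/column ids")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("lesion loads must lie in [0, 100]")
        if (self.total_volume_ml < 0).any():
            raise ValueError("total volumes must be non-negative")

    @property
    def n_patients(self) -> int:
        return len(self.row_ids)

    @property
    def n_regions(self) -> int:
        return len(self.column_ids)

    def feature(self, feature_id) -> np.ndarray:
        """Column for a region id, or total volume for ``'total_volume'``."""
        if feature_id == "total_volume":
            return self.total_volume_ml
        j = self.column_ids.index(int(feature_id))
        return self.values[:, j]

    def subset(self, patient_ids: Sequence[str]) -> "LoadMatrix":
        idx = [self.row_ids.index(p) for p in patient_ids]
        return LoadMatrix(
            values=self.values[idx],
            total_volume_ml=self.total_volume_ml[idx],
            row_ids=list(patient_ids),
            column_ids=list(self.column_ids),
            delineation_kind=self.delineation_kind,
            unlabeled_voxels=None if self.unlabeled_voxels is None else self.unlabeled_voxels[idx],
        )

    def to_frame(self, atlas: Atlas | None = None) -> pd.DataFrame:
        if atlas is not None:
            name_map = dict(zip(atlas.regions["region_id"], atlas.regions["name"]))
            cols = [name_map.get(c, f"region_{c}") for c in self.column_ids]
        else:
            cols = [f"region_{c}" for c in self.column_ids]
        df = pd.DataFrame(self.values, index=self.row_ids, columns=cols)
        df.insert(0, "patient_id", self.row_ids)
        df["total_volume_ml"] = self.total_volume_ml
        return df.reset_index(drop=True)

    def to_tsv(self, path, atlas: Atlas | None = None) -> None:
        self.to_frame(atlas).to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def region_load(mask: LesionMask, atlas: Atlas, region_id: int) -> float:
    """Percentage of the region's voxels overlapped by the lesion."""
    atlas.grid.require_compatible(mask.grid, what=f"mask for patient {mask.patient_id!r}")
    denom = atlas.region_voxel_count(int(region_id))
    if denom == 0:
        raise ValueError(f"region {region_id} has no voxels in the label volume")
    overlap = int(np.count_nonzero((atlas.labels == int(region_id)) & mask.data))
    return 100.0 * overlap / denom


def total_volume(mask: LesionMask) -> float:
    """Lesion volume in ml (voxel count times voxel volume)."""
    return mask.n_voxels * mask.grid.voxel_volume_ml


def _loads_for_mask(mask: LesionMask, atlas: Atlas, denominators: np.ndarray, ids: np.ndarray):
    # bincount over labels restricted to lesion voxels: one pass per patient
    lesioned_labels = atlas.labels[mask.data]
    counts = np.bincount(lesioned_labels, minlength=int(ids.max(initial=0)) + 1)
    overlap = counts[ids]
    unlabeled = int(lesioned_labels.size - overlap.sum())
    with np.errstate(invalid="ignore"):
        loads = np.where(denominators > 0, 100.0 * overlap / denominators, np.nan)
    return loads, unlabeled


def compute_load_matrix(
    masks: Sequence[LesionMask], atlas: Atlas, cohort: CohortTable
) -> LoadMatrix:
    """Build the cohort LoadMatrix (one row per patient, one column per region).

    All masks must share one delineation kind and the atlas grid; a patient
    without a mask is a hard error.
    """
    by_patient = {}
    for m in masks:
        atlas.grid.require_compatible(m.grid, what=f"mask for patient {m.patient_id!r}")
        if m.patient_id in by_patient:
            raise ValueError(f"duplicate mask for patient {m.patient_id!r}")
        by_patient[m.patient_id] = m
    kinds = {m.kind for m in masks}
    if len(kinds) > 1:
        raise ValueError(f"mixed delineation kinds: {sorted(kinds)}")
    kind = kinds.pop() if kinds else "followup_segmentation"

    ids = atlas.region_ids.astype(np.int64)
    zero_regions = atlas.regions.loc[atlas.regions["n_voxels"] == 0, "region_id"].tolist()
    if zero_regions:
        raise ValueError(
            f"region(s) {zero_regions} have no voxels in the label volume; "
            "load percentages are undefined for them"
        )
    denominators = atlas.regions["n_voxels"].to_numpy(dtype=np.int64)

    rows, volumes, unlabeled = [], [], []
    for record in cohort:
        mask = by_patient.get(record.patient_id)
        if mask is None:
            raise ValueError(f"no mask supplied for patient {record.patient_id!r}")
        loads, n_unlabeled = _loads_for_mask(mask, atlas, denominators, ids)
        rows.append(loads)
        volumes.append(total_volume(mask))
        unlabeled.append(n_unlabeled)

    return LoadMatrix(
        values=np.array(rows).reshape(len(cohort), len(ids)),
        total_volume_ml=np.array(volumes),
        row_ids=cohort.patient_ids,
        column_ids=[int(i) for i in ids],
        delineation_kind=kind,
        unlabeled_voxels=np.array(unlabeled, dtype=int),
    )
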