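"""Domain types and I/O for the lesion-load analysis.

Volumes live on a single common grid (the study assumes spatially normalized
images, e.g. MNI152 at 2 mm isotropic); this module holds the grid abstraction,
the atlas / mask / scalar-map / cohort containers with their validity rules,
NIfTI-1 and TSV readers/writers, and the dichotomization of the cohort by
revascularization success (TICI grade).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tolerance for grid compatibility (mm on voxel sizes, absolute on affine entries).
GRID_TOL = 1e-3
#: Values within this distance of 0/1 are snapped when reading "binary" volumes.
BINARY_TOL = 1e-6

TICI_GRADES = ("0", "1", "2a", "2b", "3")
#: Grades conventionally read as successful revascularization.
TICI_SUCCESSFUL = ("2b", "3")

MASK_KINDS = ("followup_segmentation", "adc_core", "tmax_deficit", "prediction")
SCALAR_QUANTITIES = ("adc", "tmax", "probability")


class GridMismatchError(ValueError):
    """Two volumes do not share the common analysis grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """Shape, voxel size (mm) and voxel-to-world affine of a 3D volume."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if self.affine is None:
            object.__setattr__(self, "affine", self.default_affine())
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            object.__setattr__(self, "affine", aff)

    def default_affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        # center the volume at the world origin, RAS-style
        aff[:3, 3] = -0.5 * np.asarray(self.shape) * np.asarray(self.voxel_size)
        return aff

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def compatible(self, other: "VolumeGrid", tol: float = GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.voxel_size, other.voxel_size))
            and bool(np.all(np.abs(self.affine - other.affine) <= tol))
        )

    def require_compatible(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.compatible(other):
            raise GridMismatchError(
                f"{what} grid {other.shape} @ {other.voxel_size} mm does not match the "
                f"expected grid {self.shape} @ {self.voxel_size} mm"
            )

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(img.shape[:3]), tuple(float(z) for z in zooms), np.asarray(img.affine))


@dataclass
class Atlas:
    """Labeled parcellation: integer label volume plus a region table.

    ``regions`` has columns ``region_id`` (positive int), ``name``,
    ``tissue_class`` ({gray, white}) and ``n_voxels`` (count in the label
    volume; 0 for table rows never referenced by the volume, which are kept
    but flagged).  Label 0 is background/unlabeled.
    """

    labels: np.ndarray
    grid: VolumeGrid
    regions: pd.DataFrame

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be an integer volume")
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValueError("label volume shape does not match grid")
        self.regions = self.regions.reset_index(drop=True)
        ids = self.regions["region_id"].to_numpy()
        if len(ids) == 0:
            raise ValueError("atlas must define at least one region")
        if (ids <= 0).any():
            raise ValueError("region_ids must be positive integers")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("region_ids must be unique")
        bad_class = set(self.regions["tissue_class"]) - {"gray", "white"}
        if bad_class:
            raise ValueError(f"unknown tissue_class values: {sorted(bad_class)}")
        present, counts = np.unique(self.labels, return_counts=True)
        nz = present != 0
        present, counts = present[nz], counts[nz]
        missing = set(present.tolist()) - set(ids.tolist())
        if missing:
            raise ValueError(
                f"label(s) {sorted(missing)} present in the volume but absent from the region table"
            )
        count_map = dict(zip(present.tolist(), counts.tolist()))
        self.regions["n_voxels"] = [count_map.get(int(i), 0) for i in ids]
        unreferenced = self.regions.loc[self.regions["n_voxels"] == 0, "region_id"].tolist()
        if unreferenced:
            logger.warning(
                "region table rows %s are not referenced by any voxel in the label volume",
                unreferenced,
            )

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["region_id"].to_numpy()

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_voxel_count(self, region_id: int) -> int:
        row = self.regions.loc[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"region {region_id} not in atlas")
        return int(row["n_voxels"].iloc[0])

    def brain_mask(self) -> np.ndarray:
        """Boolean mask of all labeled voxels."""
        return self.labels > 0


@dataclass
class LesionMask:
    """Binary lesion delineation for one patient on the common grid."""

    data: np.ndarray
    grid: VolumeGrid
    patient_id: str
    kind: str

    def __post_init__(self):
        arr = np.asarray(self.data)
        if tuple(arr.shape) != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if arr.dtype != bool:
            vals = arr.astype(float)
            near0 = np.abs(vals) <= BINARY_TOL
            near1 = np.abs(vals - 1.0) <= BINARY_TOL
            if not np.all(near0 | near1):
                off = vals[~(near0 | near1)]
                raise ValueError(
                    f"mask is not binary: values range [{off.min():g}, {off.max():g}] "
                    "outside tolerance of {0, 1}"
                )
            arr = near1
        self.data = arr
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown delineation kind {self.kind!r}; expected one of {MASK_KINDS}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ScalarMap:
    """Floating-point parameter map: ADC (mm^2/s), Tmax (s) or probability."""

    data: np.ndarray
    grid: VolumeGrid
    quantity: str

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if tuple(arr.shape) != self.grid.shape:
            raise ValueError("map shape does not match grid")
        if self.quantity not in SCALAR_QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; expected one of {SCALAR_QUANTITIES}"
            )
        if self.quantity == "probability":
            if arr.min() < -BINARY_TOL or arr.max() > 1 + BINARY_TOL:
                raise ValueError(
                    f"probability map values outside [0, 1]: range "
                    f"[{arr.min():g}, {arr.max():g}]"
                )
            arr = np.clip(arr, 0.0, 1.0)
        elif arr.min() < 0:
            raise ValueError(f"{self.quantity} map contains negative values")
        self.data = arr


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    tici: str
    nihss_3m: int
    mrs_3m: int
    age: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if self.tici not in TICI_GRADES:
            raise ValueError(f"unknown TICI grade {self.tici!r}; expected one of {TICI_GRADES}")
        if not (0 <= self.nihss_3m <= 42):
            raise ValueError(f"nihss_3m must be in [0, 42], got {self.nihss_3m}")
        if not (0 <= self.mrs_3m <= 6):
            raise ValueError(f"mrs_3m must be in [0, 6], got {self.mrs_3m}")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")

    @property
    def successful_revascularization(self) -> bool:
        return self.tici in TICI_SUCCESSFUL


@dataclass
class CohortTable:
    """Validated per-patient clinical records with unique patient ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def outcome(self, name: str) -> np.ndarray:
        if name not in ("nihss_3m", "mrs_3m"):
            raise ValueError(f"unknown outcome {name!r}")
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "tici": [r.tici for r in self.records],
                "nihss_3m": [r.nihss_3m for r in self.records],
                "mrs_3m": [r.mrs_3m for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _load_nifti(path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, VolumeGrid.from_nifti(img)


def read_atlas(label_volume_path, region_table_path) -> Atlas:
    """Read a labeled NIfTI volume and its TSV region table into an Atlas.

    The region table needs columns ``region_id``, ``name``, ``tissue_class``.
    Nonzero labels missing from the table are a hard error; table rows never
    referenced by the volume are kept but logged as a warning.
    """
    data, grid = _load_nifti(label_volume_path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.abs(data - rounded).max() > 1e-6:
            raise ValueError(f"{label_volume_path}: label volume has non-integer voxel values")
        data = rounded.astype(np.int32)
    table = pd.read_csv(region_table_path, sep="\t", dtype={"name": str, "tissue_class": str})
    required = {"region_id", "name", "tissue_class"}
    if not required.issubset(table.columns):
        raise ValueError(f"{region_table_path}: region table must have columns {sorted(required)}")
    table["region_id"] = table["region_id"].astype(int)
    return Atlas(labels=data, grid=grid, regions=table[["region_id", "name", "tissue_class"]])


def write_atlas(atlas: Atlas, label_volume_path, region_table_path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine)
    img.header.set_zooms(atlas.grid.voxel_size)
    nib.save(img, str(label_volume_path))
    atlas.regions[["region_id", "name", "tissue_class"]].to_csv(
        region_table_path, sep="\t", index=False
    )


def read_mask(path, expected_grid: VolumeGrid, patient_id: str = "", kind: str = MASK_KINDS[0]) -> LesionMask:
    """Read a binary lesion mask and check it sits on the expected grid."""
    data, grid = _load_nifti(path)
    expected_grid.require_compatible(grid, what=f"mask {path}")
    return LesionMask(data=data, grid=expected_grid, patient_id=patient_id, kind=kind)


def write_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.voxel_size)
    nib.save(img, str(path))


def read_scalar_map(path, expected_grid: VolumeGrid, quantity: str) -> ScalarMap:
    data, grid = _load_nifti(path)
    expected_grid.require_compatible(grid, what=f"map {path}")
    return ScalarMap(data=data, grid=expected_grid, quantity=quantity)


def write_scalar_map(smap: ScalarMap, path) -> None:
    img = nib.Nifti1Image(smap.data.astype(np.float32), smap.grid.affine)
    img.header.set_zooms(smap.grid.voxel_size)
    nib.save(img, str(path))


def read_cohort(path) -> CohortTable:
    """Read a cohort TSV (patient_id, tici, nihss_3m, mrs_3m [, age, sex])."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "tici": str, "sex": str})
    required = {"patient_id", "tici", "nihss_3m", "mrs_3m"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: cohort table must have columns {sorted(required)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    tici=str(row["tici"]),
                    nihss_3m=int(row["nihss_3m"]),
                    mrs_3m=int(row["mrs_3m"]),
                    age=float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else None,
                    sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row["sex"]) else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from exc
    try:
        return CohortTable(records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def split_by_tici(cohort: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Partition the cohort by revascularization success.

    Successful = TICI 2b or 3; unsuccessful = TICI 0, 1 or 2a.  Returns
    ``(successful, unsuccessful)``; every patient lands in exactly one part.
    """
    successful = [r for r in cohort if r.successful_revascularization]
    unsuccessful = [r for r in cohort if not r.successful_revascularization]
    return CohortTable(successful), CohortTable(unsuccessful)
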