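"""Synthetic stroke cohort with full ground truth.

The generator emulates the statistical structure the lesion-load analysis
assumes, not biophysics: an ellipsoidal brain parcellated into white-matter
(inner) and gray-matter (shell) regions with mirrored left/right homologues;
per patient a hypoperfused penumbra blob grown from a random seed voxel in
one hemisphere, an ischemic core nested inside it, and a final lesion equal
to the core plus the unsalvaged part of the penumbra — the salvaged fraction
increasing with the TICI revascularization grade, so unsuccessful
revascularization yields larger final lesions.  ADC and Tmax maps are
painted so that thresholding (ADC < 600e-6 mm^2/s, Tmax > 6 s) recovers the
core and penumbra exactly within the brain: noise amplitudes never cross the
thresholds.  A smoothed prediction map exceeds 0.5 exactly on the final
lesion.  The 3-month NIHSS is linear in the loads of a small set of
designated ("eloquent") regions plus total lesion volume, with Gaussian
noise, clipped to [0, 42] and rounded; the mRS is a noisy rescaling of the
NIHSS to [0, 6], so NIHSS tracks the loads more faithfully than mRS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import (
    Atlas,
    CohortTable,
    LesionMask,
    PatientRecord,
    ScalarMap,
    TICI_GRADES,
    VolumeGrid,
    write_atlas,
    write_cohort,
    write_mask,
    write_scalar_map,
)

#: ADC painted inside the core / elsewhere in the brain (mm^2/s); the
#: +-100e-6 uniform noise keeps both strictly on their side of 600e-6.
ADC_CORE_MEAN = 450e-6
ADC_BRAIN_MEAN = 750e-6
ADC_NOISE_HALF_WIDTH = 100e-6

#: Tmax painted inside the penumbra (9 s + U(-2, 3)) and elsewhere in the
#: brain (2 s + U(0, 3)); both stay strictly on their side of 6 s.
TMAX_PENUMBRA_MEAN = 9.0
TMAX_BRAIN_MEAN = 2.0


def _default_tici_distribution() -> dict:
    # weighted toward successful grades: ~2/3 of patients 2b-3, matching the
    # roughly 35:18 successful:unsuccessful split of a modern endovascular cohort
    return {"0": 0.06, "1": 0.08, "2a": 0.20, "2b": 0.30, "3": 0.36}


def _default_salvage() -> dict:
    return {"0": 0.0, "1": 0.10, "2a": 0.25, "2b": 0.70, "3": 0.95}


#: Default effect weight of each designated eloquent region, NIHSS points
#: per fully lesioned region.
DEFAULT_ELOQUENT_BETA = 30.0
#: Lesion seeds are drawn from brain voxels whose normalized left-right
#: coordinate exceeds this fraction of the hemisphere half-width; 0 means
#: anywhere in the hemisphere (a hemisphere-wide anterior-circulation
#: territory).
TERRITORY_MIN_LATERAL = 0.0


@dataclass
class SimulationConfig:
    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid((64, 64, 64), (2.0, 2.0, 2.0)))
    n_wm_regions: int = 29
    n_gm_regions: int = 92
    n_patients: int = 55
    tici_distribution: dict = field(default_factory=_default_tici_distribution)
    #: region_id -> NIHSS points per 100% load; None = resolve from the atlas
    #: (the two large anchored right-hemisphere structures plus one central
    #: gray parcel, beta = 30 each; see choose_eloquent_regions)
    eloquent_regions: dict | None = None
    volume_weight: float = 0.03  # NIHSS points per ml of final lesion
    baseline_nihss: float = 1.0
    noise_sd: float = 3.0  # NIHSS points
    mrs_noise_sd: float = 0.8  # mRS points on top of the rescaled NIHSS
    penumbra_salvage_by_tici: dict = field(default_factory=_default_salvage)
    penumbra_volume_ml_median: float = 90.0
    penumbra_volume_ml_sigma: float = 0.55  # sigma of log volume
    core_fraction_range: tuple = (0.2, 0.5)  # fraction of penumbra voxels in the core
    master_seed: int = 0

    def __post_init__(self):
        probs = np.array([self.tici_distribution.get(g, 0.0) for g in TICI_GRADES])
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("tici_distribution must be non-negative and sum to 1 over the five grades")
        salvage = [self.penumbra_salvage_by_tici[g] for g in TICI_GRADES]
        if any(not (0.0 <= s <= 1.0) for s in salvage):
            raise ValueError("salvaged fractions must lie in [0, 1]")
        if any(b > a for a, b in zip(salvage[1:], salvage[:-1])):
            raise ValueError("salvaged fraction must be non-decreasing in TICI grade")
        if self.noise_sd < 0 or self.mrs_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_wm_regions + self.n_gm_regions < 1:
            raise ValueError("need at least one atlas region")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {
            "shape": list(self.grid.shape),
            "voxel_size": list(self.grid.voxel_size),
        }
        if self.eloquent_regions is not None:
            d["eloquent_regions"] = {int(k): float(v) for k, v in self.eloquent_regions.items()}
        d["core_fraction_range"] = list(self.core_fraction_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = VolumeGrid(tuple(d["grid"]["shape"]), tuple(d["grid"]["voxel_size"]))
        if d.get("eloquent_regions") is not None:
            d["eloquent_regions"] = {int(k): float(v) for k, v in d["eloquent_regions"].items()}
        if "core_fraction_range" in d:
            d["core_fraction_range"] = tuple(d["core_fraction_range"])
        return cls(**d)


@dataclass
class SyntheticPatient:
    record: PatientRecord
    core_mask: LesionMask
    penumbra_mask: LesionMask
    final_mask: LesionMask
    adc_map: ScalarMap
    tmax_map: ScalarMap
    prediction_map: ScalarMap
    true_loads: dict  # region_id -> load percent of the final lesion
    noise_draw: float  # NIHSS noise actually added


@dataclass
class SyntheticCohort:
    atlas: Atlas
    cohort: CohortTable
    final_masks: list  # LesionMask per patient, cohort order
    core_masks: list
    penumbra_masks: list
    true_loads: pd.DataFrame  # patients x regions, percent
    config: SimulationConfig
    eloquent_regions: dict = field(default_factory=dict)  # resolved region_id -> beta


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

#: Relative capture radius of the anchored (territory-center) seed pair in
#: the weighted Voronoi partition; > 1 makes those regions large, extended
#: structures (tract-like), the rest roughly equal-sized parcels.
ANCHOR_SEED_WEIGHT = 2.6


def _compartment_seeds(rng, coords, x_center, n_pairs, n_midline, anchor=None):
    """Mirrored seed points: n_pairs on the right are reflected to the left,
    plus n_midline seeds near the midsagittal plane.

    If ``anchor`` is given, the first right seed is pinned to that point (and
    mirrored like the rest) and returned with an enlarged Voronoi weight, so
    the first left/right region pair models a large eloquent structure at the
    center of the lesion territory.
    """
    x = coords[:, 0]
    right = coords[x > x_center]
    if len(right) < n_pairs:
        raise ValueError("grid too small for the requested number of regions")
    sel = rng.choice(len(right), size=n_pairs, replace=False)
    right_seeds = right[sel].astype(float)
    weights_half = np.ones(n_pairs)
    if anchor is not None and n_pairs >= 1:
        right_seeds[0] = anchor
        weights_half[0] = ANCHOR_SEED_WEIGHT
    left_seeds = right_seeds.copy()
    left_seeds[:, 0] = 2 * x_center - left_seeds[:, 0]
    seeds = [right_seeds, left_seeds]
    weights = [weights_half, weights_half]
    if n_midline:
        mid = coords[np.abs(x - x_center) <= 1.5]
        if len(mid) < n_midline:
            raise ValueError("no room for midline seeds")
        sel = rng.choice(len(mid), size=n_midline, replace=False)
        seeds.append(mid[sel].astype(float))
        weights.append(np.ones(n_midline))
    return np.vstack(seeds), np.concatenate(weights)


def generate_atlas(config: SimulationConfig) -> Atlas:
    """Ellipsoidal brain: inner white-matter compartment and gray-matter shell,
    each partitioned by nearest-seed assignment with left/right-mirrored seeds.

    Region ids are 1..n_wm for white matter (right pair members first, then
    their left mirrors, then any midline region) and n_wm+1..n_wm+n_gm for
    gray matter.  Deterministic given the master seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.master_seed), 686261]))
    shape = config.grid.shape
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = 0.45 * np.asarray(shape, dtype=float)
    ii = np.indices(shape).reshape(3, -1).T.astype(float)
    r2 = (((ii - center) / semi) ** 2).sum(axis=1)
    brain = r2 <= 1.0
    white = r2 <= 0.45
    gray = brain & ~white

    labels = np.zeros(int(np.prod(shape)), dtype=np.int32)
    rows = []
    # anchors: a deep white-matter point and the overlying cortical point at
    # the center of the lateral (MCA-like) lesion territory
    anchors = {
        "white": center + np.array([0.45 * semi[0], 0.0, 0.0]),
        "gray": center + np.array([0.80 * semi[0], 0.0, 0.0]),
    }
    specs = [("white", white, config.n_wm_regions, 0), ("gray", gray, config.n_gm_regions, config.n_wm_regions)]
    for tissue, comp, n_regions, offset in specs:
        if n_regions == 0:
            continue
        coords = ii[comp]
        if len(coords) < n_regions:
            raise ValueError(f"{tissue} compartment has fewer voxels than regions")
        n_pairs, n_midline = divmod(n_regions, 2)
        seeds, weights = _compartment_seeds(
            rng, coords, center[0], n_pairs, n_midline, anchor=anchors[tissue]
        )
        # weighted (multiplicative) Voronoi: voxel joins the seed minimizing d/w
        d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2 / weights[None, :] ** 2, axis=1)
        labels[np.flatnonzero(comp)] = nearest + offset + 1
        tag = "tract" if tissue == "white" else "area"
        names = (
            [f"{tissue}_{tag}_{k + 1:02d}_R" for k in range(n_pairs)]
            + [f"{tissue}_{tag}_{k + 1:02d}_L" for k in range(n_pairs)]
            + [f"{tissue}_{tag}_median" for _ in range(n_midline)]
        )
        for j, name in enumerate(names):
            rows.append({"region_id": offset + 1 + j, "name": name, "tissue_class": tissue})
    regions = pd.DataFrame(rows)
    atlas = Atlas(labels=labels.reshape(shape), grid=config.grid, regions=regions)
    if (atlas.regions["n_voxels"] == 0).any():
        raise ValueError("seed placement produced an empty region; enlarge the grid")
    return atlas


# ---------------------------------------------------------------------------
# patients
# ---------------------------------------------------------------------------

def _territory_flat(atlas: Atlas, side: str) -> np.ndarray:
    """Flat indices of the lateral vascular territory of one hemisphere."""
    shape = atlas.grid.shape
    x_center = (shape[0] - 1) / 2.0
    semi_x = 0.45 * shape[0]
    x = np.indices(shape)[0].reshape(-1).astype(float)
    lat = (x - x_center) / semi_x  # signed, +1 at the right brain edge
    lateral = lat >= TERRITORY_MIN_LATERAL if side == "R" else lat <= -TERRITORY_MIN_LATERAL
    return np.flatnonzero(atlas.brain_mask().reshape(-1) & lateral)


def _territory_central_regions(atlas: Atlas, tissue: str, side: str, k: int) -> list:
    """Region ids of ``tissue`` whose centroids lie closest to the center of
    the lateral lesion territory of ``side``."""
    shape = atlas.grid.shape
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = 0.45 * np.asarray(shape, dtype=float)
    sgn = 1.0 if side == "R" else -1.0
    target = center + sgn * np.array([0.72 * semi[0], 0.0, 0.0])
    labels = atlas.labels.reshape(-1)
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    ids = atlas.regions.loc[atlas.regions["tissue_class"] == tissue, "region_id"].to_numpy()
    dists = []
    for rid in ids:
        centroid = coords[labels == rid].mean(axis=0)
        if sgn * (centroid[0] - center[0]) <= 0:  # wrong hemisphere
            continue
        dists.append((float(np.linalg.norm(centroid - target)), int(rid)))
    return [rid for _, rid in sorted(dists)[:k]]


def choose_eloquent_regions(atlas: Atlas, beta: float = DEFAULT_ELOQUENT_BETA) -> dict:
    """Designate eloquent regions from the atlas geometry.

    The designated set models lateralized eloquent function in a single
    (the right) hemisphere: the large anchored white-matter tract
    (corticospinal analogue), the large anchored gray-matter area overlying
    it (sensorimotor analogue) and one further territory-central gray
    parcel.  All carry equal weight ``beta`` (NIHSS points per fully
    lesioned region).  Deterministic given the atlas.
    """
    chosen: dict = {}
    white_r = atlas.regions[
        (atlas.regions["tissue_class"] == "white") & atlas.regions["name"].str.endswith("_R")
    ].sort_values("n_voxels", ascending=False)
    if white_r.empty:
        raise ValueError("atlas has no right-hemisphere white-matter region to designate")
    chosen[int(white_r["region_id"].iloc[0])] = float(beta)
    gray_r = atlas.regions[
        (atlas.regions["tissue_class"] == "gray") & atlas.regions["name"].str.endswith("_R")
    ].sort_values("n_voxels", ascending=False)
    if len(gray_r) < 2:
        raise ValueError("atlas needs two right-hemisphere gray-matter regions to designate")
    chosen[int(gray_r["region_id"].iloc[0])] = float(beta)
    for rid in _territory_central_regions(atlas, "gray", "R", 3):
        if rid not in chosen:
            chosen[rid] = float(beta)
            break
    return chosen


def resolve_eloquent_regions(config: SimulationConfig, atlas: Atlas) -> dict:
    if config.eloquent_regions is not None:
        return config.eloquent_regions
    return choose_eloquent_regions(atlas)


def _true_loads(final: np.ndarray, atlas: Atlas) -> dict:
    ids = atlas.region_ids.astype(np.int64)
    counts = np.bincount(atlas.labels[final], minlength=int(ids.max()) + 1)
    denom = atlas.regions["n_voxels"].to_numpy(dtype=np.int64)
    return {int(i): 100.0 * counts[i] / d for i, d in zip(ids, denom)}


def generate_patient(
    atlas: Atlas,
    config: SimulationConfig,
    patient_seed,
    patient_id: str = "sub-001",
    eloquent_regions: dict | None = None,
) -> SyntheticPatient:
    """Simulate one patient: lesion geometry, parameter maps and outcomes.

    ``patient_seed`` may be an int or a ``np.random.SeedSequence``.
    ``eloquent_regions`` overrides the config (used by ``generate_cohort``
    to resolve the atlas-geometry default once per cohort).
    """
    if isinstance(patient_seed, np.random.SeedSequence):
        rng = np.random.default_rng(patient_seed)
    else:
        rng = np.random.default_rng(int(patient_seed))
    grid = config.grid
    shape = grid.shape
    brain = atlas.brain_mask()
    x_center = (shape[0] - 1) / 2.0

    grades = list(TICI_GRADES)
    probs = np.array([config.tici_distribution.get(g, 0.0) for g in grades])
    tici = str(rng.choice(grades, p=probs))

    coords_all = np.indices(shape).reshape(3, -1).T
    brain_flat = brain.reshape(-1)

    # penumbra: anisotropic distance ball grown within one hemisphere from a
    # seed voxel in that hemisphere's lateral (MCA-like) territory
    for attempt in range(10):
        side = rng.choice(["L", "R"])
        hemi = coords_all[:, 0] < x_center if side == "L" else coords_all[:, 0] > x_center
        cand = np.flatnonzero(brain_flat & hemi)
        seed_cand = _territory_flat(atlas, side)
        target_ml = float(
            np.exp(rng.normal(np.log(config.penumbra_volume_ml_median), config.penumbra_volume_ml_sigma))
        )
        target_n = max(8, int(round(target_ml / grid.voxel_volume_ml)))
        if target_n <= len(cand) and len(seed_cand):
            break
    else:
        raise RuntimeError("could not fit the target penumbra volume in a hemisphere")
    seed_voxel = coords_all[rng.choice(seed_cand)]
    weights = rng.lognormal(0.0, 0.35, size=3)
    diffs = coords_all[cand] - seed_voxel
    d2 = (weights * diffs.astype(float) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    penumbra_flat = cand[order[:target_n]]  # innermost-first ordering

    core_frac = rng.uniform(*config.core_fraction_range)
    n_core = max(1, int(round(core_frac * target_n)))
    salvage = float(config.penumbra_salvage_by_tici[tici])
    n_shell_kept = int(round((1.0 - salvage) * (target_n - n_core)))
    core_flat = penumbra_flat[:n_core]
    final_flat = penumbra_flat[: n_core + n_shell_kept]  # outermost shell voxels removed first

    def as_mask(flat_idx, kind):
        m = np.zeros(shape, dtype=bool)
        m.reshape(-1)[flat_idx] = True
        return LesionMask(data=m, grid=grid, patient_id=patient_id, kind=kind)

    core = as_mask(core_flat, "adc_core")
    penumbra = as_mask(penumbra_flat, "tmax_deficit")
    final = as_mask(final_flat, "followup_segmentation")

    # parameter maps; noise amplitudes never cross the delineation thresholds
    adc = np.zeros(shape, dtype=np.float32)
    noise = rng.uniform(-ADC_NOISE_HALF_WIDTH, ADC_NOISE_HALF_WIDTH, size=int(brain.sum()))
    adc[brain] = ADC_BRAIN_MEAN + noise
    core_in_brain = core.data & brain
    adc[core_in_brain] = ADC_CORE_MEAN + rng.uniform(
        -ADC_NOISE_HALF_WIDTH, ADC_NOISE_HALF_WIDTH, size=int(core_in_brain.sum())
    )
    tmax = np.zeros(shape, dtype=np.float32)
    tmax[brain] = TMAX_BRAIN_MEAN + rng.uniform(0.0, 3.0, size=int(brain.sum()))
    pen_in_brain = penumbra.data & brain
    tmax[pen_in_brain] = TMAX_PENUMBRA_MEAN + rng.uniform(-2.0, 3.0, size=int(pen_in_brain.sum()))

    blur = ndimage.gaussian_filter(final.data.astype(np.float32), sigma=1.0)
    blur = np.clip(blur, 0.0, 1.0)
    sign = np.where(final.data, 1.0, -1.0)
    pred = np.where(brain, 0.5 + 0.45 * sign * (0.2 + 0.8 * blur), 0.0).astype(np.float32)

    loads = _true_loads(final.data, atlas)
    volume_ml = final.n_voxels * grid.voxel_volume_ml
    eloquent = resolve_eloquent_regions(config, atlas) if eloquent_regions is None else eloquent_regions
    eps = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
    linear = (
        config.baseline_nihss
        + sum(beta * loads.get(int(rid), 0.0) / 100.0 for rid, beta in eloquent.items())
        + config.volume_weight * volume_ml
        + eps
    )
    nihss = int(round(float(np.clip(linear, 0.0, 42.0))))
    mrs_noise = float(rng.normal(0.0, config.mrs_noise_sd)) if config.mrs_noise_sd > 0 else 0.0
    mrs = int(round(float(np.clip(nihss * 6.0 / 42.0 + mrs_noise, 0.0, 6.0))))

    record = PatientRecord(patient_id=patient_id, tici=tici, nihss_3m=nihss, mrs_3m=mrs)
    return SyntheticPatient(
        record=record,
        core_mask=core,
        penumbra_mask=penumbra,
        final_mask=final,
        adc_map=ScalarMap(data=adc, grid=grid, quantity="adc"),
        tmax_map=ScalarMap(data=tmax, grid=grid, quantity="tmax"),
        prediction_map=ScalarMap(data=pred, grid=grid, quantity="probability"),
        true_loads=loads,
        noise_draw=eps,
    )


def patient_seed_sequence(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), 1 + int(index)])


def generate_cohort(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    atlas: Atlas | None = None,
    keep_maps: bool = False,
) -> SyntheticCohort:
    """Simulate a full cohort; optionally write all volumes and tables to disk.

    Fully reproducible from ``config.master_seed``.  Parameter maps are
    written (if ``outdir`` is given) and then discarded unless ``keep_maps``
    — a whole cohort of float volumes is otherwise needlessly heavy.
    """
    if atlas is None:
        atlas = generate_atlas(config)
    eloquent = resolve_eloquent_regions(config, atlas)
    records, finals, cores, penumbras, load_rows, patients = [], [], [], [], [], []
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    for i in range(config.n_patients):
        pid = f"sub-{i + 1:03d}"
        patient = generate_patient(
            atlas, config, patient_seed_sequence(config.master_seed, i), pid, eloquent_regions=eloquent
        )
        records.append(patient.record)
        finals.append(patient.final_mask)
        cores.append(patient.core_mask)
        penumbras.append(patient.penumbra_mask)
        load_rows.append(patient.true_loads)
        if outdir is not None:
            vdir = outdir / "volumes"
            write_mask(patient.final_mask, vdir / f"{pid}_followup.nii.gz")
            write_mask(patient.core_mask, vdir / f"{pid}_core.nii.gz")
            write_mask(patient.penumbra_mask, vdir / f"{pid}_penumbra.nii.gz")
            write_scalar_map(patient.adc_map, vdir / f"{pid}_adc.nii.gz")
            write_scalar_map(patient.tmax_map, vdir / f"{pid}_tmax.nii.gz")
            write_scalar_map(patient.prediction_map, vdir / f"{pid}_prediction.nii.gz")
        if keep_maps:
            patients.append(patient)

    cohort = CohortTable(records)
    true_loads = pd.DataFrame(load_rows, index=cohort.patient_ids)
    true_loads.index.name = "patient_id"
    result = SyntheticCohort(
        atlas=atlas,
        cohort=cohort,
        final_masks=finals,
        core_masks=cores,
        penumbra_masks=penumbras,
        true_loads=true_loads,
        config=config,
        eloquent_regions=eloquent,
    )
    if outdir is not None:
        write_atlas(atlas, outdir / "atlas_labels.nii.gz", outdir / "atlas_regions.tsv")
        write_cohort(cohort, outdir / "cohort.tsv")
        true_loads.round(6).to_csv(outdir / "ground_truth_loads.tsv", sep="\t", lineterminator="\n")
        provenance = {
            "config": config.to_dict(),
            "true_betas": {str(k): v for k, v in eloquent.items()},
            "volume_weight": config.volume_weight,
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    if keep_maps:
        result.patients = patients  # type: ignore[attr-defined]
    return result
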