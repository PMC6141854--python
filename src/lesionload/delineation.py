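"""Threshold-based lesion delineation and cohort lesion-frequency maps.

The acute ischemic core is delineated on the apparent diffusion coefficient
map as ADC < 600e-6 mm^2/s (strict), the perfusion deficit (penumbra proxy)
as Tmax > 6 s (strict), and externally supplied continuous lesion-prediction
maps are binarized at probability >= 0.5.  A lesion-frequency map is the
voxelwise fraction of cohort masks covering each voxel.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from .core_io import LesionMask, ScalarMap

#: Default ischemic-core threshold on ADC, mm^2/s (voxels strictly below).
ADC_CORE_THRESHOLD = 600e-6
#: Default perfusion-deficit threshold on Tmax, s (voxels strictly above).
TMAX_DEFICIT_THRESHOLD = 6.0
#: Default binarization threshold for prediction maps (inclusive).
PREDICTION_THRESHOLD = 0.5


def _check_quantity(smap: ScalarMap, expected: str) -> None:
    if smap.quantity != expected:
        raise ValueError(f"expected a {expected!r} map, got {smap.quantity!r}")


def _apply_brain_mask(included: np.ndarray, brain_mask, grid) -> np.ndarray:
    if brain_mask is None:
        return included
    bm = brain_mask.data if isinstance(brain_mask, LesionMask) else np.asarray(brain_mask)
    if tuple(bm.shape) != grid.shape:
        raise ValueError("brain mask shape does not match grid")
    return included & bm.astype(bool)


def _maybe_filter_clusters(included: np.ndarray, min_cluster_size: int) -> np.ndarray:
    if min_cluster_size <= 1:
        return included
    labeled, n = ndimage.label(included)
    if n == 0:
        return included
    sizes = ndimage.sum_labels(included, labeled, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_cluster_size) + 1
    return np.isin(labeled, keep)


def delineate_adc_core(
    adc: ScalarMap,
    threshold: float = ADC_CORE_THRESHOLD,
    brain_mask=None,
    patient_id: str = "",
    min_cluster_size: int = 0,
) -> LesionMask:
    """Ischemic core: voxels with ADC strictly below ``threshold`` (mm^2/s)."""
    _check_quantity(adc, "adc")
    if threshold <= 0:
        raise ValueError("ADC threshold must be positive")
    included = adc.data < threshold
    included = _apply_brain_mask(included, brain_mask, adc.grid)
    included = _maybe_filter_clusters(included, min_cluster_size)
    return LesionMask(data=included, grid=adc.grid, patient_id=patient_id, kind="adc_core")


def delineate_tmax_deficit(
    tmax: ScalarMap,
    threshold: float = TMAX_DEFICIT_THRESHOLD,
    brain_mask=None,
    patient_id: str = "",
    min_cluster_size: int = 0,
) -> LesionMask:
    """Perfusion deficit: voxels with Tmax strictly above ``threshold`` (s)."""
    _check_quantity(tmax, "tmax")
    included = tmax.data > threshold
    included = _apply_brain_mask(included, brain_mask, tmax.grid)
    included = _maybe_filter_clusters(included, min_cluster_size)
    return LesionMask(data=included, grid=tmax.grid, patient_id=patient_id, kind="tmax_deficit")


def binarize_prediction(
    prob: ScalarMap,
    threshold: float = PREDICTION_THRESHOLD,
    brain_mask=None,
    patient_id: str = "",
    min_cluster_size: int = 0,
) -> LesionMask:
    """Binarize a continuous lesion-prediction map at ``threshold`` (inclusive)."""
    _check_quantity(prob, "probability")
    included = prob.data >= threshold
    included = _apply_brain_mask(included, brain_mask, prob.grid)
    included = _maybe_filter_clusters(included, min_cluster_size)
    return LesionMask(data=included, grid=prob.grid, patient_id=patient_id, kind="prediction")


def lesion_frequency_map(masks: Sequence[LesionMask]) -> ScalarMap:
    """Voxelwise mean of binary cohort masks.

    The result is a probability map in [0, 1]: 0 where no lesion in the
    cohort touches the voxel, 1 where every lesion covers it.
    """
    if len(masks) == 0:
        raise ValueError("lesion_frequency_map needs at least one mask")
    grid = masks[0].grid
    acc = np.zeros(grid.shape, dtype=np.float64)
    for m in masks:
        grid.require_compatible(m.grid, what=f"mask for patient {m.patient_id!r}")
        acc += m.data
    acc /= len(masks)
    return ScalarMap(data=acc, grid=grid, quantity="probability")
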