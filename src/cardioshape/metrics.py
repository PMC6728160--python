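"""Segmentation, landmark and clinical-measure evaluation.

Conventions:

* Dice of two empty masks is 1; one empty, one not is 0.
* Hausdorff distance is the symmetric max-min Euclidean distance between
  boundary voxel centres (26-connectivity surface), in mm; it is undefined
  (raises) when either mask is empty.
* Landmark error is the point-to-point Euclidean distance in world mm;
  cumulative error distribution (CED) tables report the fraction of cases
  below each threshold.
* Clinical measures: cavity volumes (LVV, RVV) are voxel counts times voxel
  volume in ml; wall masses (LVM, RVM) multiply wall volumes by the
  myocardial density (default 1.05 g/ml, the standard CMR convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import LabelMap, LandmarkSet
from .errors import CardioshapeError, GridMismatchError

__all__ = ["dice", "hausdorff", "landmark_error", "clinical_measures",
           "ClinicalMeasures", "MYOCARDIAL_DENSITY_G_PER_ML"]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


def dice(a: LabelMap, b: LabelMap, cls: int) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` of the binary masks of ``cls``."""
    if a.shape != b.shape:
        raise GridMismatchError(f"lattice mismatch {a.shape} vs {b.shape}")
    ma = a.data == cls
    mb = b.data == cls
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    return mask & ~ndimage.binary_erosion(mask, structure=struct, border_value=0)


def hausdorff(a: LabelMap, b: LabelMap, cls: int) -> float:
    """Symmetric Hausdorff distance between class boundaries, in mm."""
    if a.shape != b.shape:
        raise GridMismatchError(f"lattice mismatch {a.shape} vs {b.shape}")
    ma = a.data == cls
    mb = b.data == cls
    if not ma.any() or not mb.any():
        raise CardioshapeError(f"Hausdorff undefined: class {cls} empty in an input")
    sp = np.asarray(a.spacing)
    pa = np.argwhere(_boundary(ma)) * sp
    pb = np.argwhere(_boundary(mb)) * sp
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def landmark_error(pred: LandmarkSet, truth: LandmarkSet,
                   ced_thresholds=None) -> dict:
    """Per-landmark point-to-point error (mm) with summary statistics and a
    cumulative-error-distribution table.

    Landmarks missing from ``pred`` are reported under ``"absent"`` and
    excluded from the summary.
    """
    per = {}
    absent = []
    for name in truth.world:
        if name in pred.world:
            per[name] = float(np.linalg.norm(pred.world[name] - truth.world[name]))
        else:
            absent.append(name)
    vals = np.array(list(per.values()))
    if ced_thresholds is None:
        ced_thresholds = np.arange(0.0, 21.0, 1.0)
    ced = {}
    for t in ced_thresholds:
        ced[float(t)] = float(np.mean(vals <= t)) if vals.size else np.nan
    ced[float("inf")] = 1.0 if vals.size else np.nan
    return {
        "per_landmark": per,
        "absent": absent,
        "n_absent": len(absent),
        "mean": float(vals.mean()) if vals.size else np.nan,
        "sd": float(vals.std()) if vals.size else np.nan,
        "ced": ced,
    }


@dataclass(frozen=True)
class ClinicalMeasures:
    lvv_ml: float
    rvv_ml: float
    lvm_g: float
    rvm_g: float

    def __post_init__(self):
        for f in (self.lvv_ml, self.rvv_ml, self.lvm_g, self.rvm_g):
            if f < 0:
                raise CardioshapeError("clinical measures must be non-negative")


def clinical_measures(seg: LabelMap,
                      density: float = MYOCARDIAL_DENSITY_G_PER_ML) -> ClinicalMeasures:
    """Ventricular volumes (ml) and masses (g) from a 5-class label map."""
    voxel_ml = float(np.prod(seg.spacing)) / 1000.0  # mm^3 -> ml
    counts = np.bincount(seg.data.ravel(), minlength=seg.n_classes)
    return ClinicalMeasures(
        lvv_ml=counts[1] * voxel_ml,
        rvv_ml=counts[3] * voxel_ml,
        lvm_g=counts[2] * voxel_ml * density,
        rvm_g=counts[4] * voxel_ml * density,
    )
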