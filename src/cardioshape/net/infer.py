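"""Inference decoding: argmax label maps and landmark-centroid extraction."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..core import LANDMARK_NAMES, LabelMap, LandmarkSet, Volume
from .model import SSLLNModel

__all__ = ["predict", "extract_landmarks", "ProbabilityMaps"]


class ProbabilityMaps:
    """Per-voxel class distributions from the two softmax heads."""

    def __init__(self, seg: np.ndarray, lm: np.ndarray):
        self.seg = seg  # (N_r, X, Y, Z)
        self.lm = lm    # (N_l, X, Y, Z)


def extract_landmarks(lm_labels: np.ndarray, ref: Volume,
                      weights: np.ndarray | None = None) -> LandmarkSet:
    """Reduce each predicted landmark class to a single point: the centre of
    gravity of the largest connected component of that class.  The world
    coordinate keeps the exact (sub-voxel) mean; the voxel index is the
    rounded mean.  Classes with no voxels are simply absent from the result.

    ``weights`` (optional, shape ``(n_lm_classes,) + grid``) weights each
    voxel of class ``k`` by ``weights[k]`` when averaging — passing the
    softmax probabilities concentrates the centre of gravity on the
    prediction peak when the argmax region is large.
    """
    world, voxel = {}, {}
    for idx, name in enumerate(LANDMARK_NAMES, start=1):
        mask = lm_labels == idx
        if not mask.any():
            continue
        comp, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
            mask = comp == (int(np.argmax(sizes)) + 1)
        pts = np.argwhere(mask)
        if weights is not None:
            w = weights[idx][mask]
            centroid = (pts * w[:, None]).sum(axis=0) / max(w.sum(), 1e-12)
        else:
            centroid = pts.mean(axis=0)
        voxel[name] = tuple(int(round(c)) for c in centroid)
        world[name] = ref.voxel_to_world(centroid)[0]
    return LandmarkSet(world=world, voxel=voxel)


def predict(model: SSLLNModel, v: Volume) -> tuple[LabelMap, LandmarkSet, ProbabilityMaps]:
    """Run the network on a preprocessed volume and decode both heads by the
    per-voxel argmax along the class axis (ties resolve to the lower class
    index, i.e. towards background)."""
    p_seg, p_lm = model.forward(np.asarray(v.data, dtype=np.float64))
    seg = np.argmax(p_seg, axis=0).astype(np.int16)
    lmg = np.argmax(p_lm, axis=0).astype(np.int16)
    labels = LabelMap(data=seg, spacing=v.spacing, origin=v.origin, axes=v.axes,
                      n_classes=model.cfg.n_seg_classes)
    landmarks = extract_landmarks(lmg, v, weights=p_lm)
    return labels, landmarks, ProbabilityMaps(p_seg, p_lm)
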