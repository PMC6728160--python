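"""Low-resolution acquisition artefact simulation.

Clinical short-axis cine stacks acquired over multiple breath-holds differ
from a single-breath-hold high-resolution volume in three ways, each of which
is reproduced here to create paired corrupted/clean data:

* **large slice thickness** — the through-plane resolution drops from 2 mm to
  10 mm, producing a staircase artefact in long-axis views
  (:func:`thick_slice`);
* **inter-slice shift** — each 2D slice is independently translated in-plane,
  emulating inconsistent breath-hold positions (:func:`inter_slice_shift`);
* **lack of slice coverage** — the most apical slices are missing
  (truncation inside :func:`corrupt`).

Thick slices average the constituent thin slices for intensities (a slice-
profile approximation) and take a per-voxel majority vote for labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np

from .core import LabelMap, LandmarkSet, Volume, resample
from .errors import SpecError

__all__ = ["ArtefactSpec", "thick_slice", "inter_slice_shift", "corrupt", "corrupt_landmarks"]


@dataclass(frozen=True)
class ArtefactSpec:
    """Parameters of the simulated low-resolution acquisition."""

    target_z_spacing: float = 10.0      # mm, the clinical LR slice thickness
    max_shift_mm: float = 5.0           # in-plane breath-hold shift bound, per axis
    apical_truncation_slices: int = 0   # thick slices zeroed at the apical end
    rng_seed: int = 0

    def __post_init__(self):
        if self.max_shift_mm < 0 or self.apical_truncation_slices < 0:
            raise SpecError("artefact magnitudes must be non-negative")


def thick_slice(obj: Volume, spec: ArtefactSpec) -> Volume:
    """Downsample along the slice axis to ``target_z_spacing``.

    The in-plane grid is unchanged; the slice count drops by the spacing
    ratio.  Intensity volumes are mean-pooled over the constituent thin
    slices, label maps take the per-voxel majority (ties to the lower label).
    """
    dz = obj.spacing[2]
    if spec.target_z_spacing < dz - 1e-9:
        raise SpecError(
            f"target z spacing {spec.target_z_spacing} mm is finer than source {dz} mm"
        )
    factor = max(1, int(round(spec.target_z_spacing / dz)))
    if abs(factor * dz - spec.target_z_spacing) > 1e-6:
        # source spacing does not divide the target: bring it onto a grid that does
        obj = resample(obj, (obj.spacing[0], obj.spacing[1], spec.target_z_spacing / factor))
        dz = obj.spacing[2]
    if factor == 1:
        return obj

    nz = obj.shape[2] // factor
    blocks = np.asarray(obj.data)[:, :, : nz * factor].reshape(
        obj.shape[0], obj.shape[1], nz, factor
    )
    # the pooled slice centre sits mid-way through its block of thin slices
    origin = obj.origin + obj.axes @ np.array([0.0, 0.0, dz * (factor - 1) / 2.0])
    new_spacing = (obj.spacing[0], obj.spacing[1], dz * factor)
    if isinstance(obj, LabelMap):
        counts = np.stack([(blocks == c).sum(axis=3) for c in range(obj.n_classes)], axis=0)
        pooled = counts.argmax(axis=0).astype(np.int16)  # argmax ties -> lower label
        return LabelMap(data=pooled, spacing=new_spacing, origin=origin,
                        axes=obj.axes, n_classes=obj.n_classes)
    pooled = blocks.mean(axis=3)
    return Volume(data=pooled, spacing=new_spacing, origin=origin, axes=obj.axes)


def _draw_shifts(n_slices: int, obj: Volume, spec: ArtefactSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.rng_seed)
    max_vox = np.floor(spec.max_shift_mm / np.asarray(obj.spacing[:2])).astype(int)
    return np.stack([
        rng.integers(-max_vox[0], max_vox[0] + 1, size=n_slices),
        rng.integers(-max_vox[1], max_vox[1] + 1, size=n_slices),
    ], axis=1)


def inter_slice_shift(obj: Volume, spec: ArtefactSpec) -> tuple[Volume, np.ndarray]:
    """Translate every slice independently in-plane by an integer-voxel draw
    bounded by ``max_shift_mm``; out-of-frame voxels are zero-filled.

    Returns the degraded object and the applied per-slice (dx, dy) voxel
    shifts, so ground truth can be book-kept.  The same seed produces the
    same shifts, which is how a volume and its label map stay aligned.
    """
    data = np.asarray(obj.data)
    shifts = _draw_shifts(data.shape[2], obj, spec)
    out = np.zeros_like(data)
    nx, ny = data.shape[:2]
    for k, (dx, dy) in enumerate(shifts):
        xs_src = slice(max(0, -dx), min(nx, nx - dx))
        ys_src = slice(max(0, -dy), min(ny, ny - dy))
        xs_dst = slice(max(0, dx), min(nx, nx + dx))
        ys_dst = slice(max(0, dy), min(ny, ny + dy))
        out[xs_dst, ys_dst, k] = data[xs_src, ys_src, k]
    if isinstance(obj, LabelMap):
        res = LabelMap(data=out, spacing=obj.spacing, origin=obj.origin,
                       axes=obj.axes, n_classes=obj.n_classes)
    else:
        res = replace(obj, data=out)
    return res, shifts


def corrupt(
    v: Volume, lab: LabelMap, spec: ArtefactSpec
) -> tuple[Volume, LabelMap, dict[str, Any]]:
    """Full degradation: thick slices, then inter-slice shift, then optional
    apical truncation, applied identically to the volume and its label map.

    Metadata records the spec parameters and the per-slice shifts actually
    applied.
    """
    tv = thick_slice(v, spec)
    tl = thick_slice(lab, spec)
    sv, shifts = inter_slice_shift(tv, spec)
    sl, shifts_l = inter_slice_shift(tl, spec)
    assert np.array_equal(shifts, shifts_l)
    t = spec.apical_truncation_slices
    if t > 0:
        sv.data[:, :, :t] = 0
        sl.data[:, :, :t] = 0
    meta = {
        "target_z_spacing": spec.target_z_spacing,
        "max_shift_mm": spec.max_shift_mm,
        "apical_truncation_slices": t,
        "rng_seed": spec.rng_seed,
        "slice_shifts_vox": shifts.tolist(),
    }
    return sv, sl, meta


def corrupt_landmarks(lm: LandmarkSet, clean: Volume, corrupted: Volume,
                      meta: dict[str, Any]) -> LandmarkSet:
    """Carry landmark annotations onto the corrupted lattice: each point is
    assigned to its thick slice and moved by that slice's recorded shift."""
    shifts = np.asarray(meta["slice_shifts_vox"])
    world, voxel = {}, {}
    for name in lm.world:
        vx = np.asarray(lm.voxel.get(name, np.round(clean.world_to_voxel(lm.world[name])[0])),
                        dtype=float)
        cz = corrupted.world_to_voxel(clean.voxel_to_world(vx)[0])[0][2]
        k = int(np.clip(np.round(cz), 0, corrupted.shape[2] - 1))
        dx, dy = shifts[k]
        new_vox = np.array([vx[0] + dx, vx[1] + dy, k])
        new_vox[:2] = np.clip(new_vox[:2], 0, np.asarray(corrupted.shape[:2]) - 1)
        voxel[name] = tuple(int(round(c)) for c in new_vox)
        world[name] = corrupted.voxel_to_world(new_vox)[0]
    return LandmarkSet(world=world, voxel=voxel)
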