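"""Domain types, NIfTI I/O, preprocessing and 3D augmentation.

The in-memory containers mirror what a short-axis CMR study provides:

* :class:`Volume` — a 3D scalar intensity grid with anisotropic voxel spacing
  and a world affine (origin + direction cosines), all distances in mm.
* :class:`LabelMap` — an integer grid on the same lattice; the segmentation
  convention is 5 classes: 0 background, 1 LV cavity (LVC), 2 LV wall (LVW),
  3 RV cavity (RVC), 4 RV wall (RVW).
* :class:`LandmarkSet` — the six anatomical landmarks used to anchor the
  heart's pose, size and shape: the two RV insert points, the RV lateral-wall
  turning point, the LV lateral-wall mid-point, the apex and the centre of
  the mitral valve.

Voxel indices are 0-based; world coordinate of voxel index ``i`` is
``origin + axes @ (spacing * i)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, GridMismatchError, SpecError

__all__ = [
    "LANDMARK_NAMES",
    "N_SEG_CLASSES",
    "SEG_CLASS_NAMES",
    "Volume",
    "LabelMap",
    "LandmarkSet",
    "PreprocSpec",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "read_landmarks",
    "write_landmarks",
    "preprocess",
    "resample",
    "resample_to",
    "augment",
    "AugmentSpec",
]

#: Canonical landmark names, in class order 1..6 of the landmark label grid.
LANDMARK_NAMES = (
    "rv_insert_inferior",     # RV insert point (inferior junction of RVW and LVW)
    "rv_lateral_turn",        # RV lateral-wall turning point
    "rv_insert_anterior",     # RV insert point (anterior junction)
    "lv_lateral_mid",         # LV lateral-wall mid-point
    "apex",                   # most apical point of the LV wall
    "mitral_valve_centre",    # centre of the mitral valve (basal LVC centroid)
)

N_SEG_CLASSES = 5
SEG_CLASS_NAMES = ("background", "LVC", "LVW", "RVC", "RVW")


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(x) for x in spacing)
    if len(s) != 3 or any(x <= 0 for x in s):
        raise SpecError(f"spacing must be 3 positive floats, got {spacing!r}")
    return s


@dataclass
class Volume:
    """A 3D intensity grid with spacing (mm), origin (mm) and direction cosines."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise SpecError(f"volume data must be a 3D grid, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise SpecError("volume data must be finite")
        self.spacing = _as_spacing(self.spacing)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        A = np.eye(4)
        A[:3, :3] = self.axes * np.asarray(self.spacing)[None, :]
        A[:3, 3] = self.origin
        return A

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.affine[:3, :3] @ idx.T).T + self.origin

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine[:3, :3])
        return (inv @ (xyz - self.origin).T).T

    def same_lattice(self, other: "Volume | LabelMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )


@dataclass
class LabelMap(Volume):
    """An integer label grid on the same lattice conventions as :class:`Volume`."""

    n_classes: int = N_SEG_CLASSES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise SpecError("label map values must be integers")
            self.data = np.round(self.data).astype(np.int16)
        super().__post_init__()
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.n_classes):
            raise SpecError(
                f"label values must lie in [0, {self.n_classes}), "
                f"got range [{self.data.min()}, {self.data.max()}]"
            )

    def mask(self, cls: int) -> np.ndarray:
        return self.data == cls


@dataclass
class LandmarkSet:
    """Named 3D points: world coordinates in mm plus integer voxel indices."""

    world: dict[str, np.ndarray] = field(default_factory=dict)
    voxel: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.world = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.world.items()}
        self.voxel = {k: tuple(int(x) for x in v) for k, v in self.voxel.items()}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.world)

    @property
    def complete(self) -> bool:
        return set(self.world) == set(LANDMARK_NAMES)

    def __len__(self) -> int:
        return len(self.world)

    def points(self, names=None) -> np.ndarray:
        names = list(names) if names is not None else list(self.world)
        return np.stack([self.world[n] for n in names])

    @classmethod
    def from_voxels(cls, voxels: Mapping[str, tuple], ref: Volume) -> "LandmarkSet":
        world = {k: ref.voxel_to_world(v)[0] for k, v in voxels.items()}
        return cls(world=world, voxel=dict(voxels))

    def transformed(self, matrix: np.ndarray, translation: np.ndarray, ref: Volume | None = None) -> "LandmarkSet":
        """Apply a world-coordinate affine exactly; voxel indices re-derived from ``ref``."""
        world = {k: matrix @ p + translation for k, p in self.world.items()}
        if ref is not None:
            voxel = {k: tuple(int(round(c)) for c in ref.world_to_voxel(p)[0]) for k, p in world.items()}
        else:
            voxel = dict(self.voxel)
        return LandmarkSet(world=world, voxel=voxel)


@dataclass(frozen=True)
class PreprocSpec:
    """Reshape/clip/scale settings applied to every volume before the network.

    Volumes are clipped to the ``clip_percentiles`` range of their own
    intensity distribution, scaled to ``out_range`` and zero-padded
    symmetrically to ``target_dims``.
    """

    target_dims: tuple[int, int, int] = (192, 192, 80)
    clip_percentiles: tuple[float, float] = (1.0, 99.0)
    out_range: tuple[float, float] = (0.0, 1.0)
    allow_crop: bool = False

    def __post_init__(self):
        if self.clip_percentiles[0] >= self.clip_percentiles[1]:
            raise SpecError("clip percentile low must be < high")
        if any(d <= 0 for d in self.target_dims):
            raise SpecError("target dims must be positive")


# ---------------------------------------------------------------------------
# NIfTI and JSON I/O


def _load_nifti(path):
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    axes = linear / spacing[None, :]
    return data, tuple(spacing), affine[:3, 3].copy(), axes


def read_volume(path) -> Volume:
    """Read a NIfTI-1/2 file as an intensity :class:`Volume`."""
    data, spacing, origin, axes = _load_nifti(path)
    return Volume(data=data, spacing=spacing, origin=origin, axes=axes)


def write_volume(v: Volume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asanyarray(v.data), v.affine)
    nib.save(img, str(path))
    return path


def read_labelmap(path, n_classes: int = N_SEG_CLASSES) -> LabelMap:
    data, spacing, origin, axes = _load_nifti(path)
    return LabelMap(data=data.astype(np.int16), spacing=spacing, origin=origin,
                    axes=axes, n_classes=n_classes)


def write_labelmap(lab: LabelMap, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(lab.data.astype(np.int16), lab.affine)
    nib.save(img, str(path))
    return path


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read landmark JSON {path}: {exc}") from exc
    world = {k: np.asarray(v["world_mm"], dtype=float) for k, v in payload.items()}
    voxel = {k: tuple(int(x) for x in v["voxel"]) for k, v in payload.items()}
    return LandmarkSet(world=world, voxel=voxel)


def write_landmarks(lm: LandmarkSet, path) -> Path:
    path = Path(path)
    payload = {
        k: {"voxel": list(lm.voxel.get(k, (0, 0, 0))), "world_mm": list(map(float, lm.world[k]))}
        for k in lm.world
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess(v: Volume, spec: PreprocSpec = PreprocSpec()) -> Volume:
    """Clip intensities to the spec percentile range, scale to ``out_range``
    and zero-pad symmetrically to ``target_dims``.

    A constant volume has zero intensity range and maps to all zeros.
    Inputs larger than the target in any axis raise :class:`SpecError`
    unless ``spec.allow_crop`` enables a centre crop.
    """
    data = np.asarray(v.data, dtype=np.float64)
    lo, hi = np.percentile(data, spec.clip_percentiles)
    if hi > lo:
        scaled = (np.clip(data, lo, hi) - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(data)
    a, b = spec.out_range
    scaled = a + scaled * (b - a)

    target = spec.target_dims
    shape = scaled.shape
    if any(s > t for s, t in zip(shape, target)):
        if not spec.allow_crop:
            raise SpecError(
                f"input shape {shape} exceeds target {target}; enable allow_crop to centre-crop"
            )
        slices = []
        for s, t in zip(shape, target):
            start = max(0, (s - t) // 2)
            slices.append(slice(start, start + min(s, t)))
        scaled = scaled[tuple(slices)]
        shape = scaled.shape

    pads, offsets = [], []
    for s, t in zip(shape, target):
        before = (t - s) // 2
        pads.append((before, t - s - before))
        offsets.append(before)
    out = np.pad(scaled, pads, mode="constant", constant_values=a).astype(np.float32)
    # padding shifts the grid: move the origin so world coordinates are preserved
    shift_world = v.affine[:3, :3] @ (-np.asarray(offsets, dtype=float))
    return Volume(data=out, spacing=v.spacing, origin=v.origin + shift_world, axes=v.axes)


def resample(obj: Volume, new_spacing) -> Volume:
    """Resample to ``new_spacing`` preserving world extent to within one voxel.

    Intensity volumes are linearly interpolated; label maps use
    nearest-neighbour so the label set is preserved.
    """
    new_spacing = _as_spacing(new_spacing)
    old = np.asarray(obj.spacing)
    new = np.asarray(new_spacing)
    shape = np.asarray(obj.shape)
    new_shape = np.maximum(1, np.round(shape * old / new).astype(int))
    # voxel centres of the new grid mapped into old voxel coordinates
    coords = np.meshgrid(
        *[np.arange(n) * new[d] / old[d] for d, n in enumerate(new_shape)],
        indexing="ij",
    )
    is_label = isinstance(obj, LabelMap)
    order = 0 if is_label else 1
    out = ndimage.map_coordinates(
        np.asarray(obj.data, dtype=float), np.stack(coords), order=order, mode="nearest"
    )
    if is_label:
        return LabelMap(data=np.round(out).astype(np.int16), spacing=new_spacing,
                        origin=obj.origin, axes=obj.axes, n_classes=obj.n_classes)
    return Volume(data=out, spacing=new_spacing, origin=obj.origin, axes=obj.axes)


def resample_to(obj: Volume, ref: Volume) -> Volume:
    """Resample ``obj`` onto the lattice of ``ref`` using world coordinates
    (linear for intensities, nearest-neighbour for labels).  Voxels of ``ref``
    outside ``obj`` are filled with 0/background."""
    idx = np.indices(ref.shape).reshape(3, -1).T.astype(float)
    world = ref.voxel_to_world(idx)
    src_vox = obj.world_to_voxel(world).T
    is_label = isinstance(obj, LabelMap)
    out = ndimage.map_coordinates(np.asarray(obj.data, dtype=float), src_vox,
                                  order=0 if is_label else 1,
                                  mode="constant", cval=0.0).reshape(ref.shape)
    if is_label:
        return LabelMap(data=np.round(out).astype(np.int16), spacing=ref.spacing,
                        origin=ref.origin, axes=ref.axes, n_classes=obj.n_classes)
    return Volume(data=out, spacing=ref.spacing, origin=ref.origin, axes=ref.axes)


# ---------------------------------------------------------------------------
# On-the-fly 3D augmentation


@dataclass(frozen=True)
class AugmentSpec:
    """Random-draw ranges for on-the-fly 3D augmentation.

    Only in-plane translation, isotropic scaling and rotation about a single
    random axis through the central voxel are used — no shearing, no flips.
    """

    translate_vox: float = 10.0       # in-plane translation, U(-t, t) voxels
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotate_deg: float = 15.0          # rotation angle, U(-r, r) degrees
    intensity_range: tuple[float, float] = (0.9, 1.1)


def _world_affine_params(spec: AugmentSpec, rng: np.random.Generator):
    t = rng.uniform(-spec.translate_vox, spec.translate_vox, size=2)
    scale = rng.uniform(*spec.scale_range)
    axis = rng.integers(0, 3)
    angle = np.deg2rad(rng.uniform(-spec.rotate_deg, spec.rotate_deg))
    gain = rng.uniform(*spec.intensity_range)
    return t, scale, axis, angle, gain


def _rotation_matrix(axis: int, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s if axis != 1 else s
    R[j, i] = s if axis != 1 else -s
    return R


def augment(
    v: Volume,
    lab: LabelMap,
    lm: LandmarkSet,
    rng_seed: int,
    spec: AugmentSpec = AugmentSpec(),
) -> tuple[Volume, LabelMap, LandmarkSet]:
    """Apply one random affine (in-plane translation, isotropic scale, rotation
    about one axis through the central voxel) plus an intensity gain,
    consistently to volume, labels and landmarks.

    Labels are warped nearest-neighbour; landmark points are transformed
    exactly rather than re-sampled. Deterministic per seed.
    """
    if not v.same_lattice(lab):
        raise GridMismatchError("volume and label map must share a lattice")
    rng = np.random.default_rng(rng_seed)
    t2, scale, axis, angle, gain = _world_affine_params(spec, rng)

    S = np.diag(v.spacing)
    Sinv = np.diag(1.0 / np.asarray(v.spacing))
    R = _rotation_matrix(axis, angle)
    centre_vox = (np.asarray(v.shape) - 1) / 2.0
    # forward map in voxel space: x' = M (x - c) + c + t
    M = Sinv @ (scale * R) @ S
    t_vox = np.array([t2[0], t2[1], 0.0])

    Minv = np.linalg.inv(M)
    offset = centre_vox - Minv @ (centre_vox + t_vox)

    vdata = np.asarray(v.data)
    if not np.issubdtype(vdata.dtype, np.floating):
        vdata = vdata.astype(np.float32)
    warped = ndimage.affine_transform(
        vdata, Minv, offset=offset, order=1, mode="constant", cval=0.0
    )
    warped_lab = ndimage.affine_transform(
        lab.data, Minv, offset=offset, order=0, mode="constant", cval=0, output=lab.data.dtype
    )

    new_world = {}
    new_voxel = {}
    names = set(lm.world) | set(lm.voxel)
    for name in names:
        if name in lm.world:  # prefer the exact continuous position
            x = v.world_to_voxel(lm.world[name])[0]
        else:
            x = np.asarray(lm.voxel[name], dtype=float)
        xv = M @ (x - centre_vox) + centre_vox + t_vox
        new_voxel[name] = tuple(int(round(c)) for c in xv)
        new_world[name] = v.voxel_to_world(xv)[0]

    out_v = replace(v, data=warped * gain)
    out_lab = LabelMap(data=warped_lab, spacing=lab.spacing, origin=lab.origin,
                       axes=lab.axes, n_classes=lab.n_classes)
    return out_v, out_lab, LandmarkSet(world=new_world, voxel=new_voxel)
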