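"""Synthetic bi-ventricular phantom cohorts and atlas banks.

The clinical cohorts behind this pipeline (high-resolution healthy hearts and
a pulmonary-hypertension cohort) are not publicly deposited, so the package
ships a geometric phantom that emulates their statistical structure: a left
ventricle modelled as two coaxial truncated ellipsoids (cavity + wall), and a
crescentic right ventricle formed by a larger, laterally shifted ellipsoid
clipped against the LV epicardium.  Per-class intensity means plus Gaussian
noise give an MR-like appearance (bright blood pools, mid-grey myocardium),
and pose/size/shape are randomised per subject.

Landmarks are placed by continuous geometric rules in the heart frame and
then mapped through the pose transform, so that a rigid change of pose moves
every landmark by exactly that transform.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import (
    LANDMARK_NAMES,
    LabelMap,
    LandmarkSet,
    Volume,
    read_labelmap,
    read_landmarks,
    read_volume,
    write_labelmap,
    write_landmarks,
    write_volume,
)
from .errors import SpecError, ValidationError

__all__ = ["PhantomSpec", "Atlas", "AtlasBank", "make_phantom", "make_cohort",
           "build_atlas_bank", "save_bank", "load_bank", "save_cohort", "load_cohort"]

# class intensity means on the [0, 1] preprocessed scale (b-SSFP-like:
# blood pools bright, myocardium mid-grey, air/lung background dark)
DEFAULT_MEANS = {0: 0.15, 1: 0.95, 2: 0.50, 3: 0.85, 4: 0.42}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, pose and intensity model of one synthetic bi-ventricular heart.

    All lengths in mm.  The default models an adult-size heart (apex-to-base
    80 mm) on a compact lattice with the standard 2 mm high-resolution slice
    spacing; the in-plane spacing (2 mm) is coarser than a clinical 1.25 mm
    acquisition to keep whole-cohort experiments CPU-friendly.
    """

    grid_dims: tuple[int, int, int] = (80, 80, 50)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lv_endo_radius: float = 22.0      # LV cavity in-plane semi-axis at the base
    lv_epi_radius: float = 30.0       # LV epicardial in-plane semi-axis
    rv_radius: float = 30.0           # RV epicardial ellipsoid in-plane semi-axis
    rv_offset: float = 24.0           # lateral shift of the RV ellipsoid centre
    rv_wall_thickness: float = 5.0    # RV free-wall thickness (thinner than LVW)
    extent: float = 80.0              # apex-to-base length
    rv_extent_frac: float = 0.85      # RV length relative to LV length
    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_means: tuple[float, ...] = tuple(DEFAULT_MEANS[k] for k in range(5))
    noise_sd: float = 0.04
    blur_sigma: float = 0.5   # partial-volume blur of the class-mean image, voxels
    rng_seed: int = 0

    def __post_init__(self):
        if self.lv_epi_radius <= self.lv_endo_radius:
            raise SpecError("LV epicardial radius must exceed endocardial radius")
        if self.rv_wall_thickness >= self.lv_epi_radius - self.lv_endo_radius + 1e-9:
            # RV free wall thinner than the LV wall, mirroring normal anatomy
            raise SpecError("RV wall must be thinner than the LV wall")
        if self.extent <= 0:
            raise SpecError("apex-to-base extent must be positive")

    @classmethod
    def ph_like(cls, **overrides) -> "PhantomSpec":
        """Pulmonary-hypertension-like morphology: dilated RV, thickened RV
        wall, compressed LV cavity."""
        base = cls(**overrides)
        return replace(
            base,
            rv_radius=base.rv_radius * 1.3,
            rv_offset=base.rv_offset * 1.15,
            rv_wall_thickness=min(base.rv_wall_thickness + 1.0,
                                  base.lv_epi_radius - base.lv_endo_radius - 0.5),
            lv_endo_radius=base.lv_endo_radius * 0.85,
        )


@dataclass
class Atlas:
    """One shape-prior unit: intensity volume, label map and 6 landmarks."""

    volume: Volume
    labels: LabelMap
    landmarks: LandmarkSet
    subject_id: str = ""


@dataclass
class AtlasBank:
    entries: list[Atlas] = field(default_factory=list)
    provenance: str = "phantom"       # phantom | network-predicted

    def __len__(self) -> int:
        return len(self.entries)


def _pose_matrices(spec: PhantomSpec):
    """World <-> heart-frame maps. heart frame: origin at the basal LV centre,
    z axis from base (0) towards the apex (-extent)."""
    rx, ry, rz = np.deg2rad(spec.rotations_deg)

    def rot(axis, a):
        c, s = np.cos(a), np.sin(a)
        R = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        R[i, i] = R[j, j] = c
        sign = -1.0 if axis == 1 else 1.0
        R[i, j] = -s * sign
        R[j, i] = s * sign
        return R

    R = rot(2, rz) @ rot(1, ry) @ rot(0, rx)
    dims = np.asarray(spec.grid_dims)
    sp = np.asarray(spec.spacing)
    centre_world = (dims - 1) / 2.0 * sp
    # basal centre sits half the extent above the volume centre along the heart z axis
    base_world = centre_world + R @ np.array([0.0, 0.0, spec.extent / 2.0]) \
        + np.asarray(spec.translations_mm)
    return R, base_world


def _heart_frame_coords(spec: PhantomSpec):
    R, base = _pose_matrices(spec)
    dims = spec.grid_dims
    sp = np.asarray(spec.spacing)
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in dims], indexing="ij")
    world = np.stack([ii * sp[0], jj * sp[1], kk * sp[2]], axis=-1)
    h = (world - base) @ R  # R^T applied row-wise
    return h, R, base


def _radius_profile(r_base: float, z: np.ndarray, extent: float) -> np.ndarray:
    """In-plane semi-axis of a half-ellipsoid of basal radius r_base and
    length `extent` at heart-frame depth z in [-extent, 0]."""
    frac = np.clip(1.0 - (z / extent) ** 2, 0.0, None)
    return r_base * np.sqrt(frac)


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap, LandmarkSet]:
    """Rasterise one phantom: intensity volume, 5-class label map, 6 landmarks."""
    h, R, base = _heart_frame_coords(spec)
    x, y, z = h[..., 0], h[..., 1], h[..., 2]
    wall = spec.lv_epi_radius - spec.lv_endo_radius
    in_slab = (z <= 0) & (z >= -spec.extent)

    def inside(r_base, extent, cx=0.0):
        ext = np.maximum(extent, 1e-6)
        q = ((x - cx) ** 2 + y ** 2) / np.maximum(
            _radius_profile(r_base, np.clip(z, -ext + 1e-6, 0.0), ext), 1e-9) ** 2
        return in_slab & (z >= -ext) & (q <= 1.0)

    lv_endo = inside(spec.lv_endo_radius, spec.extent - wall)
    lv_epi = inside(spec.lv_epi_radius, spec.extent)
    rv_ext = spec.extent * spec.rv_extent_frac
    rv_epi = inside(spec.rv_radius, rv_ext, cx=spec.rv_offset)
    rv_endo = inside(spec.rv_radius - spec.rv_wall_thickness,
                     rv_ext - spec.rv_wall_thickness, cx=spec.rv_offset)

    lab = np.zeros(spec.grid_dims, dtype=np.int16)
    lab[rv_epi & ~rv_endo & ~lv_epi] = 4
    lab[rv_endo & ~lv_epi] = 3
    lab[lv_epi & ~lv_endo] = 2
    lab[lv_endo] = 1
    _absorb_fragments(lab)

    for cls in range(5):
        if not np.any(lab == cls):
            raise SpecError(f"phantom geometry does not fit the grid: class {cls} empty")
    border = np.zeros_like(lab, dtype=bool)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    if np.any((lab > 0) & border):
        raise SpecError("phantom geometry does not fit the grid: foreground touches the border")

    means = np.asarray(spec.intensity_means)
    rng = np.random.default_rng(spec.rng_seed)
    mean_img = means[lab]
    if spec.blur_sigma > 0:
        mean_img = ndimage.gaussian_filter(mean_img, sigma=spec.blur_sigma)
    data = mean_img + (rng.standard_normal(lab.shape) * spec.noise_sd
                       if spec.noise_sd > 0 else 0.0)

    vol = Volume(data=data, spacing=spec.spacing)
    labels = LabelMap(data=lab, spacing=spec.spacing, n_classes=5)
    lm = _place_landmarks(spec, labels, R, base)
    return vol, labels, lm


def _absorb_fragments(lab: np.ndarray) -> None:
    """Reassign rasterisation slivers (components other than the largest of a
    class) to the most common neighbouring label, keeping each ventricular
    class singly connected."""
    for cls in range(1, 5):
        comp, n = ndimage.label(lab == cls)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones(lab.shape), comp, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        frag = (comp > 0) & (comp != keep)
        grown = ndimage.grey_dilation(np.where(lab == cls, -1, lab), size=3)
        lab[frag] = np.maximum(grown[frag], 0)


def _place_landmarks(spec: PhantomSpec, labels: LabelMap, R, base) -> LandmarkSet:
    """Continuous geometric landmark rules in the heart frame, mapped by pose."""
    wall = spec.lv_epi_radius - spec.lv_endo_radius
    z_mb = -0.35 * spec.extent     # mid-basal slice for the RV landmarks
    z_mid = -0.5 * spec.extent     # mid-ventricular slice for the LV lateral point

    rL = _radius_profile(spec.lv_epi_radius, np.array(z_mb), spec.extent).item()
    rv_ext = spec.extent * spec.rv_extent_frac
    rR = _radius_profile(spec.rv_radius, np.array(max(z_mb, -rv_ext + 1e-6)), rv_ext).item()
    d = spec.rv_offset
    # intersection of the LV-epi circle (radius rL at 0) and RV-epi circle
    # (radius rR at (d, 0)): the two RV insert points
    x0 = (d * d + rL * rL - rR * rR) / (2 * d)
    y0_sq = max(rL * rL - x0 * x0, 0.0)
    y0 = float(np.sqrt(y0_sq))

    r_endo_mid = _radius_profile(spec.lv_endo_radius, np.array(z_mid),
                                 spec.extent - wall).item()
    r_epi_mid = _radius_profile(spec.lv_epi_radius, np.array(z_mid), spec.extent).item()

    # pull the insert points from the epicardial tangent onto the LV wall
    # mid-surface so the snapped voxel lands inside tissue
    shrink = (rL - wall / 2.0) / rL
    heart_pts = {
        "rv_insert_inferior": np.array([x0 * shrink, -y0 * shrink, z_mb]),
        "rv_lateral_turn": np.array([d + rR - spec.rv_wall_thickness / 2.0, 0.0, z_mb]),
        "rv_insert_anterior": np.array([x0 * shrink, y0 * shrink, z_mb]),
        "lv_lateral_mid": np.array([-(r_endo_mid + r_epi_mid) / 2.0, 0.0, z_mid]),
        "apex": np.array([0.0, 0.0, -(spec.extent - wall / 2.0)]),
        "mitral_valve_centre": np.array([0.0, 0.0, -1.5 * np.asarray(spec.spacing)[2]]),
    }
    world = {k: R @ p + base for k, p in heart_pts.items()}
    ref = labels
    voxel = {}
    dims = np.asarray(spec.grid_dims)
    for k, p in world.items():
        v = np.clip(np.round(ref.world_to_voxel(p)[0]).astype(int), 0, dims - 1)
        voxel[k] = tuple(int(c) for c in v)
    return LandmarkSet(world=world, voxel=voxel)


def make_cohort(
    n: int,
    base_spec: PhantomSpec = PhantomSpec(),
    variability: float = 1.0,
    rng_seed: int = 0,
) -> list[tuple[Volume, LabelMap, LandmarkSet]]:
    """Generate ``n`` phantoms with independently jittered size, pose and shape.

    ``variability`` linearly scales every jitter range; 0 reproduces the base
    spec exactly.  Reproducible per seed.
    """
    if n < 1:
        raise SpecError("cohort size must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n):
        s = variability
        jit = lambda lo, hi: rng.uniform(lo, hi) * s  # noqa: E731
        size = 1 + jit(-0.08, 0.08)  # global heart size factor
        lv_endo = base_spec.lv_endo_radius * size * (1 + jit(-0.06, 0.06))
        wall = (base_spec.lv_epi_radius - base_spec.lv_endo_radius) * size * (1 + jit(-0.10, 0.10))
        rv_wall = min(base_spec.rv_wall_thickness * (1 + jit(-0.10, 0.10)), wall - 0.3)
        spec = replace(
            base_spec,
            lv_endo_radius=lv_endo,
            lv_epi_radius=lv_endo + wall,
            rv_wall_thickness=rv_wall,
            rv_radius=base_spec.rv_radius * size * (1 + jit(-0.06, 0.06)),
            rv_offset=base_spec.rv_offset * size * (1 + jit(-0.06, 0.06)),
            extent=base_spec.extent * (1 + jit(-0.08, 0.08)),
            rotations_deg=tuple(np.asarray(base_spec.rotations_deg)
                                + np.array([jit(-5, 5), jit(-5, 5), jit(-15, 15)])),
            translations_mm=tuple(np.asarray(base_spec.translations_mm)
                                  + np.array([jit(-4, 4), jit(-4, 4), jit(-2, 2)])),
            rng_seed=base_spec.rng_seed + i,
        )
        out.append(make_phantom(spec))
    return out


def build_atlas_bank(cohort, provenance: str = "phantom") -> AtlasBank:
    """Assemble (volume, labels, landmarks) triples into an atlas bank.

    Every entry must carry a complete 6-landmark set; the first missing
    landmark is reported by subject and name.
    """
    entries = []
    for i, (vol, lab, lm) in enumerate(cohort):
        sid = f"subject_{i:03d}"
        for name in LANDMARK_NAMES:
            if name not in lm.world:
                raise ValidationError(f"{sid}: landmark '{name}' missing")
        entries.append(Atlas(volume=vol, labels=lab, landmarks=lm, subject_id=sid))
    return AtlasBank(entries=entries, provenance=provenance)


# ---------------------------------------------------------------------------
# Disk round-trips: NIfTI volumes + landmark JSON + CSV manifest


def save_cohort(cohort, out_dir, seeds=None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (vol, lab, lm) in enumerate(cohort):
        sid = f"subject_{i:03d}"
        write_volume(vol, out_dir / f"{sid}_volume.nii.gz")
        write_labelmap(lab, out_dir / f"{sid}_labels.nii.gz")
        write_landmarks(lm, out_dir / f"{sid}_landmarks.json")
        spec_hash = hashlib.sha256(
            json.dumps([vol.shape, vol.spacing], default=str).encode()).hexdigest()[:12]
        rows.append([sid, seeds[i] if seeds else "", spec_hash])
    with open(out_dir / "manifest.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["subject_id", "seed", "spec_hash"])
        w.writerows(rows)
    return out_dir


def load_cohort(in_dir) -> list[tuple[Volume, LabelMap, LandmarkSet]]:
    in_dir = Path(in_dir)
    out = []
    with open(in_dir / "manifest.csv") as f:
        for row in csv.DictReader(f):
            sid = row["subject_id"]
            out.append((
                read_volume(in_dir / f"{sid}_volume.nii.gz"),
                read_labelmap(in_dir / f"{sid}_labels.nii.gz"),
                read_landmarks(in_dir / f"{sid}_landmarks.json"),
            ))
    return out


def save_bank(bank: AtlasBank, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for a in bank.entries:
        write_volume(a.volume, out_dir / f"{a.subject_id}_volume.nii.gz")
        write_labelmap(a.labels, out_dir / f"{a.subject_id}_labels.nii.gz")
        write_landmarks(a.landmarks, out_dir / f"{a.subject_id}_landmarks.json")
        rows.append([a.subject_id])
    with open(out_dir / "manifest.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["subject_id"])
        w.writerows(rows)
    (out_dir / "bank.json").write_text(json.dumps({"provenance": bank.provenance}))
    return out_dir


def load_bank(in_dir) -> AtlasBank:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "bank.json").read_text()) if (in_dir / "bank.json").exists() else {}
    entries = []
    with open(in_dir / "manifest.csv") as f:
        for row in csv.DictReader(f):
            sid = row["subject_id"]
            entries.append(Atlas(
                volume=read_volume(in_dir / f"{sid}_volume.nii.gz"),
                labels=read_labelmap(in_dir / f"{sid}_labels.nii.gz"),
                landmarks=read_landmarks(in_dir / f"{sid}_landmarks.json"),
                subject_id=sid,
            ))
    return AtlasBank(entries=entries, provenance=meta.get("provenance", "phantom"))
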