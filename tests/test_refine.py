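"""Shape refinement: landmark affine, NMI atlas selection, label-consistency
FFD registration and non-local patch label fusion."""

import numpy as np
import pytest
from scipy import ndimage

from cardioshape.core import LabelMap, LandmarkSet, Volume
from cardioshape.errors import DegenerateGeometryError, GridMismatchError, SpecError
from cardioshape.metrics import dice
from cardioshape.phantom import PhantomSpec, build_atlas_bank, make_cohort, make_phantom
from cardioshape.refine import (AffineTransform, FFDTransform, FusionSpec,
                                RegistrationSpec, affine_from_landmarks,
                                fuse_labels, label_consistency, nmi, refine,
                                register_ffd, select_atlases, warp_atlas)
from cardioshape.refine import _spline_weight_matrix

from conftest import small_phantom_spec
from oracles import fuse_labels_loop


def _points(seed, n=6, scale=50.0):
    rng = np.random.default_rng(seed)
    return {f"p{i}": rng.uniform(0, scale, 3) for i in range(n)}


class TestAffineFromLandmarks:
    def test_identity_when_targets_equal_sources(self):
        pts = _points(0)
        aff = affine_from_landmarks(LandmarkSet(world=pts), LandmarkSet(world=pts))
        np.testing.assert_allclose(aff.matrix, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(aff.translation, 0.0, atol=1e-9)
        assert aff.residual == pytest.approx(0.0, abs=1e-18)

    def test_exact_recovery_of_known_affine(self):
        pts = _points(1)
        M = np.diag([1.2, 0.9, 1.1])
        t = np.array([3.0, -2.0, 5.0])
        dst = LandmarkSet(world={k: M @ p + t for k, p in pts.items()})
        aff = affine_from_landmarks(LandmarkSet(world=pts), dst)
        assert np.abs(aff.matrix - M).max() < 1e-8
        assert np.abs(aff.translation - t).max() < 1e-8

    def test_noise_degrades_gracefully(self):
        """Monte-Carlo: with isotropic 1 mm landmark noise the residual stays
        within the total injected noise power."""
        pts = _points(2)
        rng = np.random.default_rng(3)
        sd = 1.0
        residuals, errors = [], []
        for _ in range(100):
            dst = LandmarkSet(world={k: p + rng.normal(0, sd, 3)
                                     for k, p in pts.items()})
            aff = affine_from_landmarks(LandmarkSet(world=pts), dst)
            residuals.append(aff.residual)
            errors.append(np.abs(aff.matrix - np.eye(3)).max())
        assert 0.0 <= np.mean(residuals) <= 6 * 3 * sd ** 2
        assert np.mean(errors) < 1.0  # transform stays near identity

    def test_too_few_correspondences_rejected(self):
        pts = _points(4, n=3)
        with pytest.raises(DegenerateGeometryError):
            affine_from_landmarks(LandmarkSet(world=pts), LandmarkSet(world=pts))

    def test_coplanar_configuration_rejected(self):
        pts = {f"p{i}": np.array([i * 1.0, i * 2.0 % 7, 0.0]) for i in range(6)}
        with pytest.raises(DegenerateGeometryError, match="coplanar"):
            affine_from_landmarks(LandmarkSet(world=pts), LandmarkSet(world=pts))


class TestAtlasSelection:
    @pytest.fixture(scope="class")
    def bank(self, small_spec):
        return build_atlas_bank(make_cohort(4, small_spec, rng_seed=11))

    def test_identical_target_ranks_first_with_nmi_two(self, bank):
        atlas = bank.entries[2]
        ranked = select_atlases(atlas.labels, bank, atlas.landmarks, L=4)
        assert ranked[0][0].subject_id == atlas.subject_id
        assert ranked[0][2] == pytest.approx(2.0, abs=1e-9)

    def test_l_equal_bank_size_returns_all_sorted(self, bank):
        atlas = bank.entries[0]
        ranked = select_atlases(atlas.labels, bank, atlas.landmarks, L=4)
        scores = [s for *_, s in ranked]
        assert len(ranked) == 4
        assert scores == sorted(scores, reverse=True)

    def test_oversized_l_truncates_with_warning(self, bank):
        atlas = bank.entries[0]
        with pytest.warns(UserWarning):
            ranked = select_atlases(atlas.labels, bank, atlas.landmarks, L=99)
        assert len(ranked) == 4

    def test_empty_bank_rejected(self, bank):
        from cardioshape.phantom import AtlasBank
        atlas = bank.entries[0]
        with pytest.raises(SpecError):
            select_atlases(atlas.labels, AtlasBank(), atlas.landmarks, L=1)

    def test_nmi_of_a_map_with_itself_is_two(self, small_phantom):
        _, lab, _ = small_phantom
        assert nmi(lab.data, lab.data) == pytest.approx(2.0)


class TestLabelConsistency:
    def test_equal_maps_score_one(self, small_phantom):
        _, lab, _ = small_phantom
        assert label_consistency(lab, lab) == 1.0

    def test_fully_disagreeing_maps_score_zero(self):
        a = LabelMap(data=np.ones((4, 4, 1), dtype=np.int16))
        b = LabelMap(data=np.full((4, 4, 1), 2, dtype=np.int16))
        assert label_consistency(a, b) == 0.0

    def test_hand_counted_toy_pair(self):
        a = np.zeros((4, 4, 1), dtype=np.int16)
        b = np.zeros((4, 4, 1), dtype=np.int16)
        b.ravel()[:6] = 1  # disagree on 6 of 16 voxels
        assert label_consistency(LabelMap(data=a), LabelMap(data=b)) == 0.625

    def test_lattice_mismatch_raises(self):
        a = LabelMap(data=np.zeros((4, 4, 1), dtype=np.int16))
        b = LabelMap(data=np.zeros((4, 4, 2), dtype=np.int16))
        with pytest.raises(GridMismatchError):
            label_consistency(a, b)


def _synthetic_ffd_warp(lab, spacing_mm, magnitude, seed):
    Ws = [_spline_weight_matrix(n, spacing_mm / sp)
          for n, sp in zip(lab.shape, lab.spacing)]
    rng = np.random.default_rng(seed)
    D = rng.uniform(-magnitude, magnitude,
                    (3,) + tuple(W.shape[1] for W in Ws))
    dense = np.stack([np.einsum("ai,bj,ck,ijk->abc", Ws[0], Ws[1], Ws[2], D[d],
                                optimize=True) for d in range(3)])
    idx = np.indices(lab.shape).astype(float)
    warped = ndimage.map_coordinates(lab.data.astype(float),
                                     (idx + dense).reshape(3, -1), order=0,
                                     mode="constant").reshape(lab.shape)
    return LabelMap(data=np.round(warped).astype(np.int16), spacing=lab.spacing,
                    n_classes=lab.n_classes)


class TestRegisterFFD:
    SPEC = RegistrationSpec(levels_mm=(24.0, 12.0), max_iters=20,
                            smooth_sigma=(1.0, 0.5))

    def test_identity_optimum_stays_near_identity(self, small_phantom):
        _, lab, _ = small_phantom
        ffd = register_ffd(lab, lab, AffineTransform.identity(), self.SPEC)
        assert ffd.max_displacement_vox < 0.5

    def test_recovers_synthetic_warp(self, small_phantom):
        """Warp-and-recover: registering the original labels onto a known
        FFD-warped copy restores LVC overlap above 0.95."""
        _, lab, _ = small_phantom
        target = _synthetic_ffd_warp(lab, 16.0, 3.0, seed=5)
        before = dice(target, lab, 1)
        ffd = register_ffd(target, lab, AffineTransform.identity(), self.SPEC)
        vol = Volume(data=lab.data.astype(float), spacing=lab.spacing)
        _, warped = warp_atlas(vol, lab, ffd, target)
        after = dice(target, warped, 1)
        assert after >= 0.95
        assert after > before

    def test_agreement_monotone_within_levels_and_gated(self, small_phantom):
        _, lab, _ = small_phantom
        target = _synthetic_ffd_warp(lab, 20.0, 1.8, seed=6)
        ffd = register_ffd(target, lab, AffineTransform.identity(), self.SPEC)
        for level_hist in ffd.history:
            assert all(b >= a - 1e-12 for a, b in zip(level_hist, level_hist[1:]))
        assert ffd.hard_agreement >= ffd.initial_hard_agreement

    def test_label_permutation_covariance(self, small_phantom):
        """Consistently relabelling both inputs leaves the transform unchanged."""
        _, lab, _ = small_phantom
        target = _synthetic_ffd_warp(lab, 20.0, 1.5, seed=7)
        perm = np.array([0, 3, 4, 1, 2])
        ffd = register_ffd(target, lab, AffineTransform.identity(), self.SPEC)
        lab_p = LabelMap(data=perm[lab.data], spacing=lab.spacing)
        tgt_p = LabelMap(data=perm[target.data], spacing=target.spacing)
        ffd_p = register_ffd(tgt_p, lab_p, AffineTransform.identity(), self.SPEC)
        np.testing.assert_allclose(ffd.dense_total, ffd_p.dense_total, atol=1e-9)

    def test_singular_init_rejected(self, small_phantom):
        _, lab, _ = small_phantom
        with pytest.raises(DegenerateGeometryError):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))


class TestFuseLabels:
    def _random_instance(self, seed, n_atlases=3, shape=(6, 6, 4)):
        rng = np.random.default_rng(seed)
        target = Volume(data=rng.random(shape))
        warped = []
        for _ in range(n_atlases):
            av = Volume(data=rng.random(shape))
            al = LabelMap(data=rng.integers(0, 5, shape), n_classes=5)
            warped.append((av, al))
        return target, warped

    @pytest.mark.parametrize("seed", range(6))
    def test_bit_identical_to_exhaustive_loop(self, seed):
        target, warped = self._random_instance(seed)
        h = 0.31
        fused = fuse_labels(target, warped,
                            FusionSpec(patch_radius=1, window_radius=1, h=h))
        ref = fuse_labels_loop(np.asarray(target.data),
                               [np.asarray(av.data) for av, _ in warped],
                               [al.data for _, al in warped], 1, 1, h)
        np.testing.assert_array_equal(fused.data, ref)

    def test_infinite_bandwidth_is_majority_vote(self):
        target, warped = self._random_instance(99)
        fused = fuse_labels(target, warped,
                            FusionSpec(patch_radius=1, window_radius=1, h=1e15))
        votes = np.zeros((5,) + target.data.shape)
        for _, al in warped:
            for off in np.ndindex(3, 3, 3):
                o = tuple(x - 1 for x in off)
                src = [slice(max(0, d), min(s, s + d)) for d, s in zip(o, al.data.shape)]
                dst = [slice(max(0, -d), min(s, s - d)) for d, s in zip(o, al.data.shape)]
                shifted = np.full(al.data.shape, -1)
                shifted[tuple(dst)] = al.data[tuple(src)]
                for k in range(5):
                    votes[k][shifted == k] += 1
        np.testing.assert_array_equal(fused.data, votes.argmax(axis=0))

    def test_single_identical_atlas_zero_window_returns_its_labels(self):
        rng = np.random.default_rng(5)
        vol = Volume(data=rng.random((5, 5, 3)))
        lab = LabelMap(data=rng.integers(0, 5, (5, 5, 3)), n_classes=5)
        fused = fuse_labels(vol, [(vol, lab)],
                            FusionSpec(patch_radius=1, window_radius=0))
        np.testing.assert_array_equal(fused.data, lab.data)

    def test_no_label_invention(self):
        target, warped = self._random_instance(7)
        for _, al in warped:
            al.data[al.data == 4] = 3  # remove class 4 from every atlas
        fused = fuse_labels(target, warped,
                            FusionSpec(patch_radius=1, window_radius=1))
        assert 4 not in np.unique(fused.data)

    def test_empty_atlas_list_rejected(self):
        with pytest.raises(SpecError):
            fuse_labels(Volume(data=np.zeros((4, 4, 2))), [], FusionSpec())


class TestRefine:
    REG = RegistrationSpec(levels_mm=(16.0,), max_iters=8, smooth_sigma=1.0)
    FUS = FusionSpec(patch_radius=1, window_radius=1)

    def test_self_refinement_keeps_bank_member_shape(self, small_spec):
        bank = build_atlas_bank(make_cohort(4, small_spec, rng_seed=21))
        target = bank.entries[1]
        vol = target.volume
        out = refine(vol, target.labels, target.landmarks, bank,
                     self.FUS, self.REG, L=3)
        for cls in range(1, 5):
            assert dice(out, target.labels, cls) >= 0.98

    def test_refined_output_singly_connected(self, small_spec):
        bank = build_atlas_bank(make_cohort(4, small_spec, rng_seed=22))
        target = bank.entries[0]
        out = refine(target.volume, target.labels, target.landmarks, bank,
                     self.FUS, self.REG, L=3)
        for cls in range(1, 5):
            assert ndimage.label(out.data == cls)[1] == 1

    def test_disease_like_targets_select_disease_like_atlases(self, small_spec):
        """A dilated-RV target against a mixed healthy/disease-like bank must
        rank mostly disease-like atlases first, so fusion cannot vote the
        pathology away."""
        from dataclasses import asdict
        geo = {k: getattr(small_spec, k) for k in
               ("grid_dims", "spacing", "lv_endo_radius", "lv_epi_radius",
                "rv_radius", "rv_offset", "rv_wall_thickness", "extent")}
        ph_spec = PhantomSpec.ph_like(**geo)
        healthy = make_cohort(3, small_spec, rng_seed=31)
        diseased = make_cohort(3, ph_spec, rng_seed=32)
        bank = build_atlas_bank(healthy + diseased)
        t_vol, t_lab, t_lm = make_phantom(ph_spec)
        ranked = select_atlases(t_lab, bank, t_lm, L=3)
        picked = [a.subject_id for a, *_ in ranked]
        n_diseased = sum(int(sid.split("_")[1]) >= 3 for sid in picked)
        assert n_diseased >= 2
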