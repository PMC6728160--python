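"""The multi-task training objective, checked against literal scalar-loop
implementations of the printed formulas."""

import numpy as np
import pytest

from cardioshape.core import LandmarkSet
from cardioshape.errors import GridMismatchError
from cardioshape.net import (dice_loss, landmark_loss, landmark_weights,
                             rasterise_landmarks, total_loss)
from cardioshape.net.losses import one_hot

from oracles import dice_loss_loop, landmark_loss_loop


def random_probs(shape, n_classes, seed):
    rng = np.random.default_rng(seed)
    z = rng.random((n_classes,) + shape)
    return z / z.sum(axis=0)


class TestDiceLoss:
    EPS = 1e-5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 5, (8, 8, 4))
        prob = random_probs((8, 8, 4), 5, seed + 10)
        ours = dice_loss(prob, truth, eps=self.EPS)
        ref = dice_loss_loop(prob, truth, eps=self.EPS)
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_perfect_one_hot_prediction_approaches_minus_one(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 5, (6, 6, 3))
        prob = one_hot(truth, 5)
        v = truth.size
        expected = -2 * v / (2 * v + self.EPS * v * 5)
        assert dice_loss(prob, truth, eps=self.EPS) == pytest.approx(expected)
        assert dice_loss(prob, truth, eps=self.EPS) == pytest.approx(-1.0, abs=1e-4)

    def test_disjoint_one_hot_prediction_is_zero(self):
        truth = np.zeros((4, 4, 2), dtype=int)
        wrong = one_hot(np.ones((4, 4, 2), dtype=int), 5)
        assert dice_loss(wrong, truth) == pytest.approx(0.0)

    def test_uniform_prediction_matches_oracle(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 5, (4, 4, 4))
        prob = np.full((5, 4, 4, 4), 1 / 5)
        assert dice_loss(prob, truth, eps=self.EPS) == pytest.approx(
            dice_loss_loop(prob, truth, eps=self.EPS), rel=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 3, (4, 4, 2))
        prob = random_probs((4, 4, 2), 3, 6)
        _, grad = dice_loss(prob, truth, return_grad=True)
        h = 1e-7
        for idx in [(0, 0, 0, 0), (1, 2, 3, 1), (2, 1, 0, 1)]:
            p1 = prob.copy(); p1[idx] += h
            p2 = prob.copy(); p2[idx] -= h
            num = (dice_loss(p1, truth) - dice_loss(p2, truth)) / (2 * h)
            assert grad[idx] == pytest.approx(num, rel=1e-4)

    def test_lattice_mismatch_raises(self):
        with pytest.raises(GridMismatchError):
            dice_loss(np.zeros((5, 4, 4, 4)), np.zeros((4, 4, 2), dtype=int))

    def test_per_class_variant_gradient(self):
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 3, (4, 4, 2))
        prob = random_probs((4, 4, 2), 3, 9)
        val, grad = dice_loss(prob, truth, return_grad=True, per_class=True)
        h = 1e-7
        idx = (1, 1, 1, 1)
        p1 = prob.copy(); p1[idx] += h
        p2 = prob.copy(); p2[idx] -= h
        num = (dice_loss(p1, truth, per_class=True)
               - dice_loss(p2, truth, per_class=True)) / (2 * h)
        assert grad[idx] == pytest.approx(num, rel=1e-4)


class TestLandmarkWeights:
    def test_full_grid_arithmetic(self):
        grid = np.zeros((192, 192, 80), dtype=np.int16)
        total = grid.size
        assert total == 2_949_120
        for c, vox in zip(range(1, 7), [(0, 0, 0), (1, 1, 1), (2, 2, 2),
                                        (3, 3, 3), (4, 4, 4), (5, 5, 5)]):
            grid[vox] = c
        w = landmark_weights(grid)
        for c in range(1, 7):
            assert w[c] == 1.0 - 1.0 / total
        assert w[0] == pytest.approx(6.0 / total)

    def test_weights_are_exactly_one_minus_frequency(self):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 7, (10, 10, 5))
        w = landmark_weights(grid)
        for c in range(7):
            assert w[c] == 1.0 - (grid == c).sum() / grid.size


class TestLandmarkLoss:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 7, (8, 8, 4))
        prob = random_probs((8, 8, 4), 7, seed + 20)
        assert landmark_loss(prob, labels) == pytest.approx(
            landmark_loss_loop(prob, labels), rel=1e-6)

    def test_perfect_confident_prediction_is_zero(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 7, (6, 6, 2))
        assert landmark_loss(one_hot(labels, 7), labels) == pytest.approx(0.0)

    def test_zero_probability_is_clamped_finite(self):
        labels = np.zeros((4, 4, 2), dtype=int)
        labels[0, 0, 0] = 3
        prob = one_hot(np.zeros_like(labels), 7)  # class 3 has probability 0
        val = landmark_loss(prob, labels)
        assert np.isfinite(val)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, (4, 4, 2))
        prob = random_probs((4, 4, 2), 4, 4)
        _, grad = landmark_loss(prob, labels, return_grad=True)
        h = 1e-7
        idx = (2, 1, 1, 1)
        p1 = prob.copy(); p1[idx] += h
        p2 = prob.copy(); p2[idx] -= h
        num = (landmark_loss(p1, labels) - landmark_loss(p2, labels)) / (2 * h)
        assert grad[idx] == pytest.approx(num, rel=1e-4)


class TestWeightInvariants:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.integers(0, 6), min_size=8, max_size=64))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_complement_weights_sum_to_classes_minus_one(self, labels):
        """Since the class frequencies sum to 1, the weights 1 - |Y_k|/|Y|
        always sum to n_classes - 1, whatever the grid."""
        grid = np.asarray(labels, dtype=np.int16).reshape(-1, 1, 1)
        w = landmark_weights(grid, n_classes=7)
        assert float(w.sum()) == pytest.approx(6.0)
        assert np.all((0.0 <= w) & (w <= 1.0))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=10)
    def test_dice_loss_bounded_and_sign_definite(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 5, (6, 6, 2))
        prob = random_probs((6, 6, 2), 5, seed)
        val = dice_loss(prob, truth)
        assert -1.0 <= val <= 0.0


class TestTotalLoss:
    def test_alpha_beta_zero_reduces_to_dice(self):
        assert total_loss(-0.7, 5.0, 3.0, alpha=0.0, beta=0.0) == -0.7

    def test_sum_of_task_losses(self):
        assert total_loss(-0.7, 5.0, 3.0, alpha=1.0, beta=0.0) == pytest.approx(4.3)

    def test_alpha_scales_landmark_term_linearly(self):
        base = total_loss(-0.5, 2.0, 0.0, alpha=1.0, beta=0.0)
        double = total_loss(-0.5, 2.0, 0.0, alpha=2.0, beta=0.0)
        assert double - base == pytest.approx(2.0)


class TestRasterisationBalance:
    def test_landmark_and_background_contributions_same_order(self, small_phantom):
        """The class weights exist to balance 6 voxels against ~30k: with an
        untrained (uniform) prediction the summed landmark-class terms and
        the background term are within one order of magnitude."""
        _, lab, lm = small_phantom
        grid = rasterise_landmarks(lm, lab.shape, dilation=0)
        prob = np.full((7,) + lab.shape, 1 / 7)
        w = landmark_weights(grid)
        contrib = np.zeros(7)
        for k in range(7):
            contrib[k] = -w[k] * np.log(1 / 7) * (grid == k).sum()
        fg, bg = contrib[1:].sum(), contrib[0]
        assert 0.1 < fg / bg < 10.0

    def test_rasterise_single_voxel_per_landmark(self, small_phantom):
        _, lab, lm = small_phantom
        grid = rasterise_landmarks(lm, lab.shape, dilation=0)
        counts = np.bincount(grid.ravel(), minlength=7)
        assert np.all(counts[1:] == 1)

    def test_dilation_grows_support(self, small_phantom):
        _, lab, lm = small_phantom
        g0 = rasterise_landmarks(lm, lab.shape, dilation=0)
        g1 = rasterise_landmarks(lm, lab.shape, dilation=1)
        assert (g1 > 0).sum() > (g0 > 0).sum()
        # dilation never overwrites another landmark's voxel
        assert np.all(g1[g0 > 0] == g0[g0 > 0])
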