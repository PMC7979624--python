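"""Analytic loss identities, hand-evaluated oracles and agreement metrics."""

import math
import warnings

import numpy as np
import pytest

from bodycomp import nn
from bodycomp.losses_metrics import (LossConfig, bland_altman, combined_loss,
                                     dice_score, generalized_dice_loss, icc,
                                     mean_foreground_dice, xce_loss)
from bodycomp.volume_io import IGNORE


def one_hot_probs(labels, n_classes=6):
    """Probability field putting mass 1 on the true class everywhere."""
    lab = np.asarray(labels)
    p = np.zeros((n_classes,) + lab.shape, dtype=np.float32)
    for c in range(n_classes):
        p[c][lab == c] = 1.0
    return p


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self, rng):
        lab = rng.integers(0, 6, size=(3, 4, 4)).astype(np.uint8)
        assert xce_loss(one_hot_probs(lab), lab) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_is_log_c(self):
        lab = np.zeros((2, 3, 3), np.uint8)
        p = np.full((6, 2, 3, 3), 1 / 6, np.float32)
        assert xce_loss(p, lab) == pytest.approx(math.log(6), rel=1e-5)

    def test_ignored_voxels_excluded_from_normalizer(self):
        # 10 voxels, 5 ignored, remaining 5 predicted at 0.5 on the true
        # class: -(1/5) * 5 * log(0.5) = log 2
        lab = np.zeros((1, 1, 10), np.uint8)
        lab[0, 0, 5:] = IGNORE
        p = np.full((6, 1, 1, 10), 0.1, np.float32)
        p[0] = 0.5
        assert xce_loss(p, lab) == pytest.approx(math.log(2), rel=1e-5)

    def test_all_ignored_warns_and_returns_zero(self):
        lab = np.full((1, 2, 2), IGNORE, np.uint8)
        p = np.full((6, 1, 2, 2), 1 / 6, np.float32)
        with pytest.warns(UserWarning, match="ignore"):
            assert xce_loss(p, lab) == 0.0


class TestDiceLoss:
    def test_perfect_one_hot_is_zero(self, rng):
        lab = rng.integers(0, 6, size=(4, 4, 4)).astype(np.uint8)
        assert generalized_dice_loss(one_hot_probs(lab), lab) == pytest.approx(
            0.0, abs=1e-6)

    def test_disjoint_prediction_approaches_one(self):
        # truth cycles through all foreground classes; the prediction puts
        # its mass on a different foreground class at every voxel
        lab = (np.arange(4 * 8 * 8, dtype=np.uint8) % 5 + 1).reshape(4, 8, 8)
        p = np.zeros((6, 4, 8, 8), np.float32)
        shifted = lab % 5 + 1
        p[shifted, *np.indices(lab.shape)] = 1.0
        loss = generalized_dice_loss(p, lab, LossConfig(epsilon=1e-7))
        assert loss == pytest.approx(1.0, abs=1e-4)

    def test_class_absent_from_both_is_not_penalized(self):
        # truth all class 1, prediction all class 2: classes 3..5 untouched
        # contribute eps/eps = 1 each -> loss = 1 - 3/5 = 0.4
        lab = np.ones((4, 8, 8), np.uint8)
        p = np.zeros((6, 4, 8, 8), np.float32)
        p[2] = 1.0
        loss = generalized_dice_loss(p, lab, LossConfig(epsilon=1e-7))
        assert loss == pytest.approx(0.4, abs=1e-5)

    def test_four_voxel_hand_oracle(self):
        # C=3, N=4: evaluated by direct substitution into the formula.
        p = np.array([[0.7, 0.2, 0.1, 0.4],
                      [0.2, 0.5, 0.3, 0.3],
                      [0.1, 0.3, 0.6, 0.3]], np.float32).reshape(3, 1, 1, 4)
        lab = np.array([0, 1, 2, 1], np.uint8).reshape(1, 1, 4)
        eps = 1e-5
        # class 1: num = 2*(0.5+0.3)+eps, den = 1.3+2+eps
        # class 2: num = 2*0.6+eps,       den = 1.3+1+eps
        expected = 1.0 - 0.5 * ((1.6 + eps) / (3.3 + eps)
                                + (1.2 + eps) / (2.3 + eps))
        got = generalized_dice_loss(p, lab, LossConfig(epsilon=eps))
        assert got == pytest.approx(expected, rel=1e-6)

    def test_epsilon_converges_to_smoothing_free_value(self, rng):
        lab = rng.integers(0, 6, size=(4, 16, 16)).astype(np.uint8)
        p = np.full((6, 4, 16, 16), 1 / 6, np.float32)
        l_free = generalized_dice_loss(p, lab, LossConfig(epsilon=1e-12))
        l_small = generalized_dice_loss(p, lab, LossConfig(epsilon=1e-5))
        l_big = generalized_dice_loss(p, lab, LossConfig(epsilon=1.0))
        assert l_small == pytest.approx(l_free, abs=1e-5)
        assert abs(l_big - l_free) < 0.05
        assert abs(l_small - l_free) <= abs(l_big - l_free)

    def test_loss_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            lab = rng.integers(0, 6, size=(2, 4, 4)).astype(np.uint8)
            logits = rng.normal(size=(6, 2, 4, 4)).astype(np.float32)
            e = np.exp(logits)
            p = e / e.sum(axis=0, keepdims=True)
            assert 0.0 <= generalized_dice_loss(p, lab) <= 1.0

    def test_permutation_invariance(self, rng):
        lab = rng.integers(0, 6, size=(1, 1, 64)).astype(np.uint8)
        p = rng.dirichlet(np.ones(6), size=64).T.astype(np.float32)
        p = p.reshape(6, 1, 1, 64)
        perm = rng.permutation(64)
        a = generalized_dice_loss(p, lab)
        b = generalized_dice_loss(p[..., perm], lab[..., perm])
        assert a == pytest.approx(b, rel=1e-5)
        assert xce_loss(p, lab) == pytest.approx(
            xce_loss(p[..., perm], lab[..., perm]), rel=1e-5)


class TestCombinedLoss:
    def test_perfect_prediction_is_zero(self, rng):
        lab = rng.integers(0, 6, size=(2, 4, 4)).astype(np.uint8)
        assert combined_loss(one_hot_probs(lab), lab) == pytest.approx(0, abs=1e-6)

    def test_equal_weighting_of_components(self, rng):
        lab = rng.integers(0, 6, size=(2, 4, 4)).astype(np.uint8)
        p = np.full((6, 2, 4, 4), 1 / 6, np.float32)
        cfg = LossConfig()
        expected = 0.5 * xce_loss(p, lab) + 0.5 * generalized_dice_loss(p, lab, cfg)
        assert combined_loss(p, lab, cfg) == pytest.approx(expected, rel=1e-6)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LossConfig(w_xce=0.7, w_dice=0.5)

    def test_all_ignored_degenerate_case(self):
        lab = np.full((1, 2, 2), IGNORE, np.uint8)
        p = np.full((6, 1, 2, 2), 1 / 6, np.float32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert combined_loss(p, lab) == pytest.approx(0.0, abs=1e-6)

    def test_ignored_voxels_have_zero_gradient(self, rng):
        lab = rng.integers(0, 6, size=(2, 4, 4)).astype(np.uint8)
        lab[0, :2] = IGNORE
        logits = nn.Tensor(rng.normal(size=(6, 2, 4, 4)).astype(np.float32),
                           requires_grad=True)
        loss = combined_loss(nn.functional.softmax_channels(logits), lab)
        loss.backward()
        np.testing.assert_allclose(logits.grad[:, lab == IGNORE], 0.0, atol=0)
        assert np.any(logits.grad[:, lab != IGNORE] != 0)


class TestDiceScore:
    def test_identical_masks(self, small_phantom):
        _, truth = small_phantom
        assert dice_score(truth.dense, truth.dense, 1) == 1.0
        assert mean_foreground_dice(truth.dense, truth.dense) == 1.0

    def test_disjoint_equal_masks(self):
        a = np.zeros((1, 2, 4), np.uint8)
        b = np.zeros((1, 2, 4), np.uint8)
        a[0, 0] = 1
        b[0, 1] = 1
        assert dice_score(a, b, 1) == 0.0

    def test_hand_counted_overlap(self):
        # P has 2 voxels of class 1, T has 4, overlap 2 -> 2*2/(2+4)
        p = np.zeros((1, 1, 8), np.uint8)
        t = np.zeros((1, 1, 8), np.uint8)
        p[0, 0, :2] = 1
        t[0, 0, :4] = 1
        assert dice_score(p, t, 1) == pytest.approx(2 * 2 / (2 + 4))

    def test_symmetry(self, rng):
        a = rng.integers(0, 6, size=(2, 4, 4)).astype(np.uint8)
        b = rng.integers(0, 6, size=(2, 4, 4)).astype(np.uint8)
        for c in range(6):
            assert dice_score(a, b, c) == dice_score(b, a, c)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((1, 2, 2), np.uint8)
        assert dice_score(z, z, 5) == 1.0

    def test_ignored_voxels_excluded(self):
        p = np.zeros((1, 1, 4), np.uint8)
        t = np.zeros((1, 1, 4), np.uint8)
        p[0, 0, 0] = 1          # disagreement only on an ignored voxel
        t[0, 0, 0] = IGNORE
        assert dice_score(p, t, 1) == 1.0

    def test_unknown_class_rejected(self):
        z = np.zeros((1, 2, 2), np.uint8)
        with pytest.raises(ValueError, match="unknown class"):
            dice_score(z, z, 9)


class TestICC:
    def test_identical_series_is_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_constant_shift_penalized(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc(a, a + 2.0) < 1.0

    def test_six_point_hand_anova_oracle(self):
        # Frozen from an independent two-way ANOVA decomposition:
        # MSR, MSC, MSE computed by hand for these numbers give
        # ICC(2,1) = (MSR-MSE)/(MSR + MSE + 2*(MSC-MSE)/6) = 0.9906716...
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [1.1, 2.3, 2.8, 4.4, 4.9, 6.3]
        assert icc(a, b) == pytest.approx(0.9906716417910458, rel=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            icc([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            icc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_diff == 0.0
        assert ba.loa_low == ba.loa_high == 0.0

    def test_known_bias(self):
        ba = bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert ba.mean_diff == pytest.approx(1.0)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-12)
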