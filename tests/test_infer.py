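"""Sliding-window planning, weighted blending and ensemble averaging."""

from dataclasses import dataclass

import numpy as np
import pytest

from bodycomp.infer import (InferenceConfig, argmax_labels, ensemble_predict,
                            plan_windows, sliding_window_predict, window_weights)
from bodycomp.models import ModelConfig, build_model
from bodycomp.preprocess import PreprocessConfig, WindowSpec, stack_and_center
from bodycomp.phantom import PhantomConfig, generate_phantom
from bodycomp.volume_io import CTVolume


@dataclass
class _StubConfig:
    depth: int = 0
    n_classes: int = 2
    in_channels: int = 1


class _ConstantModel:
    """Returns the same class distribution at every voxel."""

    def __init__(self, dist, depth=0):
        self.dist = np.asarray(dist, np.float32)
        self.config = _StubConfig(depth=depth, n_classes=len(dist))

    def predict_proba(self, x):
        out = np.empty((len(self.dist),) + x.shape[1:], np.float32)
        out[:] = self.dist[:, None, None, None]
        return out


class _ZMarkerModel:
    """Emits a value derived from the window content so overlapping windows
    disagree and the blending arithmetic becomes observable."""

    def __init__(self):
        self.config = _StubConfig(depth=0, n_classes=2)

    def predict_proba(self, x):
        m = float(x.mean())  # differs between windows
        p1 = 1.0 / (1.0 + np.exp(-m))
        out = np.empty((2,) + x.shape[1:], np.float32)
        out[0] = 1 - p1
        out[1] = p1
        return out


class TestPlanWindows:
    @pytest.mark.parametrize("n,expected", [
        (32, [0]),
        (40, [0, 8]),
        (45, [0, 8, 13]),   # final window clamped to 45-32
        (16, [0]),          # shorter than one window
        (33, [0, 1]),
    ])
    def test_examples(self, n, expected):
        assert plan_windows(n, InferenceConfig()) == expected

    def test_stride_is_quarter_window(self):
        assert InferenceConfig().stride == 8

    def test_every_slice_covered_and_end_aligned(self):
        cfg = InferenceConfig()
        for n in range(1, 150):
            starts = plan_windows(n, cfg)
            covered = np.zeros(max(n, cfg.window_slices), bool)
            for s in starts:
                covered[s:s + cfg.window_slices] = True
            assert covered[:n].all(), n
            assert starts[-1] + cfg.window_slices >= n


class TestWindowWeights:
    @pytest.mark.parametrize("profile", ["uniform", "triangular", "gaussian"])
    def test_positive_and_symmetric(self, profile):
        w = window_weights(InferenceConfig(weighting=profile))
        assert (w > 0).all()
        np.testing.assert_allclose(w, w[::-1], rtol=1e-12)

    def test_triangular_peaks_at_center(self):
        w = window_weights(InferenceConfig(weighting="triangular"))
        assert w[0] == 1.0 and w.max() == w[15] == w[16] == 16.0


class TestSlidingWindow:
    def _small_pre(self):
        return PreprocessConfig(windows=(WindowSpec(-1024, 3071),),
                                downscale_factor=1)

    @pytest.mark.parametrize("profile", ["uniform", "triangular", "gaussian"])
    def test_constant_model_reproduced_exactly(self, profile):
        ct = CTVolume(voxels=np.zeros((12, 8, 8), np.int16), spacing=(5, 1, 1))
        model = _ConstantModel([0.3, 0.7])
        cfg = InferenceConfig(window_slices=4, overlap_fraction=0.75,
                              weighting=profile)
        out = sliding_window_predict(model, ct, self._small_pre(), cfg)
        np.testing.assert_allclose(out[0], 0.3, atol=1e-6)
        np.testing.assert_allclose(out[1], 0.7, atol=1e-6)

    def test_single_window_equals_direct_call(self):
        cfg = PhantomConfig(shape=(16, 8, 8), spacing=(5.0, 50.0, 50.0))
        ct, _ = generate_phantom(cfg, seed=2)
        model = build_model(ModelConfig(family="unet3d", n_f=2, depth=1,
                                        in_channels=1, n_classes=6, seed=0))
        pre = self._small_pre()
        inf = InferenceConfig(window_slices=16)
        out = sliding_window_predict(model, ct, pre, inf)
        direct = model.predict_proba(stack_and_center(ct, pre))
        np.testing.assert_allclose(out, direct, atol=1e-5)

    def test_two_window_weighted_average_matches_hand_formula(self):
        """Blend of overlapping windows must equal sum(w*p)/sum(w) per slice."""
        nz, ws = 6, 4
        ct = CTVolume(voxels=np.arange(nz * 4 * 4, dtype=np.int16).reshape(nz, 4, 4),
                      spacing=(5, 1, 1))
        model = _ZMarkerModel()
        pre = self._small_pre()
        cfg = InferenceConfig(window_slices=ws, overlap_fraction=0.75)
        starts = plan_windows(nz, cfg)
        assert starts == [0, 1, 2]
        out = sliding_window_predict(model, ct, pre, cfg)

        # independent re-aggregation from the stub's per-window outputs
        x = stack_and_center(ct, pre)
        weights = window_weights(cfg)
        num = np.zeros(nz)
        den = np.zeros(nz)
        for s in starts:
            p = model.predict_proba(x[:, s:s + ws])
            num[s:s + ws] += weights * p[1, :, 0, 0]
            den[s:s + ws] += weights
        np.testing.assert_allclose(out[1, :, 0, 0], num / den, rtol=1e-5)

    def test_simplex_preserved_after_upsampling(self, small_phantom):
        ct, _ = small_phantom
        model = build_model(ModelConfig(family="unet3d", n_f=2, depth=2, seed=0))
        out = sliding_window_predict(model, ct, PreprocessConfig(),
                                     InferenceConfig(window_slices=8))
        assert out.shape == (6,) + ct.shape
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-4)

    def test_volume_thinner_than_window_padded(self):
        ct = CTVolume(voxels=np.zeros((3, 8, 8), np.int16), spacing=(5, 1, 1))
        model = _ConstantModel([0.5, 0.5])
        out = sliding_window_predict(model, ct, self._small_pre(),
                                     InferenceConfig(window_slices=8))
        assert out.shape == (2, 3, 8, 8)


class TestEnsemble:
    def test_mean_of_two_constant_models(self):
        ct = CTVolume(voxels=np.zeros((4, 8, 8), np.int16), spacing=(5, 1, 1))
        pre = PreprocessConfig(windows=(WindowSpec(-1024, 3071),), downscale_factor=1)
        cfg = InferenceConfig(window_slices=4)
        out = ensemble_predict([_ConstantModel([0.8, 0.2]),
                                _ConstantModel([0.6, 0.4])], ct, pre, cfg)
        np.testing.assert_allclose(out[0], 0.7, atol=1e-6)
        np.testing.assert_allclose(out[1], 0.3, atol=1e-6)

    def test_identical_models_idempotent(self):
        ct = CTVolume(voxels=np.zeros((4, 8, 8), np.int16), spacing=(5, 1, 1))
        pre = PreprocessConfig(windows=(WindowSpec(-1024, 3071),), downscale_factor=1)
        cfg = InferenceConfig(window_slices=4)
        single = ensemble_predict([_ConstantModel([0.3, 0.7])], ct, pre, cfg)
        five = ensemble_predict([_ConstantModel([0.3, 0.7])] * 5, ct, pre, cfg)
        np.testing.assert_allclose(single, five, atol=1e-7)

    def test_mismatched_class_counts_rejected(self):
        ct = CTVolume(voxels=np.zeros((4, 8, 8), np.int16), spacing=(5, 1, 1))
        with pytest.raises(ValueError, match="class count"):
            ensemble_predict([_ConstantModel([1.0]), _ConstantModel([0.5, 0.5])], ct)

    def test_empty_ensemble_rejected(self):
        ct = CTVolume(voxels=np.zeros((4, 8, 8), np.int16), spacing=(5, 1, 1))
        with pytest.raises(ValueError, match="at least one"):
            ensemble_predict([], ct)


class TestArgmax:
    def test_one_hot_field_recovers_labels(self, rng):
        lab = rng.integers(0, 6, size=(2, 3, 3))
        p = np.zeros((6, 2, 3, 3), np.float32)
        for c in range(6):
            p[c][lab == c] = 1.0
        np.testing.assert_array_equal(argmax_labels(p).labels, lab)

    def test_tie_broken_toward_lowest_class(self):
        p = np.zeros((6, 1, 1, 1), np.float32)
        p[1] = p[4] = 0.5
        assert argmax_labels(p).labels[0, 0, 0] == 1

    def test_uniform_field_is_background(self):
        p = np.full((6, 1, 2, 2), 1 / 6, np.float32)
        assert (argmax_labels(p).labels == 0).all()
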