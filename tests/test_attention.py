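"""Math core: class-activation maps, soft masks, IoU losses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from attnguide import (
    AttentionMap,
    ClassScores,
    FeatureStack,
    LossConfig,
    attention_loss,
    classification_loss,
    compute_gradcam,
    soft_iou,
    soft_mask,
    total_loss,
)
from attnguide import autodiff as ad
from attnguide.attention import SoftMask


def _pixel_iou(a, b):
    """Independent pixel-counting IoU oracle for binary grids."""
    a = a.astype(bool)
    b = b.astype(bool)
    union = (a | b).sum()
    return (a & b).sum() / union if union else 0.0


class TestComputeGradcam:
    def test_zero_gradients_zero_map(self, rng):
        maps = rng.normal(size=(3, 4, 4))
        fs = FeatureStack(maps=maps, gradients=np.zeros_like(maps))
        out = compute_gradcam(fs, LossConfig())
        np.testing.assert_array_equal(out.values, np.zeros((4, 4)))

    def test_constant_gradient_weights(self, rng):
        a = rng.normal(size=(2, 2))
        b = rng.normal(size=(2, 2))
        grads = np.stack([np.full((2, 2), 2.0), np.full((2, 2), -1.0)])
        fs = FeatureStack(maps=np.stack([a, b]), gradients=grads)
        out = compute_gradcam(fs, LossConfig(gradcam_relu=False))
        np.testing.assert_allclose(out.values, 2 * a - b, atol=1e-12)

    def test_relu_applied_by_default(self):
        maps = np.array([[[-1.0, 1.0], [0.5, -0.5]]])
        fs = FeatureStack(maps=maps, gradients=np.ones_like(maps))
        out = compute_gradcam(fs, LossConfig())
        assert out.values.min() >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FeatureStack(maps=np.zeros((2, 3, 3)), gradients=np.zeros((2, 4, 4)))

    def test_matches_cam_on_gap_linear_toy_network(self, rng):
        """Grad-CAM == closed-form CAM for a conv -> GAP -> linear net.

        Gradients are obtained by reverse-mode autodiff through the toy
        network; the oracle computes the head-weight-weighted feature sum
        directly.  They agree up to the GAP factor 1/(m*n).
        """
        x = rng.normal(size=(1, 1, 10, 12))
        wc = ad.Tensor(rng.normal(size=(4, 1, 3, 3)))
        head = rng.normal(size=(3, 4))
        feats = ad.relu(ad.conv2d(ad.Tensor(x, requires_grad=True), wc, stride=1))
        pooled = ad.tmean(feats, axis=(2, 3))
        logits = ad.matmul(pooled, ad.Tensor(head.T))
        target = 1
        logits[0, target].backward()
        grads = feats.grad[0]
        fs = FeatureStack(maps=feats.data[0], gradients=grads)
        gc = compute_gradcam(fs, LossConfig(gradcam_relu=False))
        m, n = feats.data.shape[2:]
        cam = np.tensordot(head[target], feats.data[0], axes=(0, 0))
        np.testing.assert_allclose(gc.values * (m * n), cam, atol=1e-5)


class TestSoftMask:
    def test_entry_at_threshold_is_half(self):
        cfg = LossConfig(theta=0.5, omega=100.0)
        amap = AttentionMap(values=np.array([[0.0, 0.5], [1.0, 0.25]]))
        sm = soft_mask(amap, (2, 2), cfg)
        assert sm.values[0, 1] == pytest.approx(0.5, abs=1e-5)

    def test_saturated_high_entry(self):
        cfg = LossConfig(theta=0.5, omega=100.0)
        amap = AttentionMap(values=np.array([[0.0, 1.0]]))
        sm = soft_mask(amap, (1, 2), cfg)
        assert abs(sm.values[0, 1] - 1.0) < 1e-15

    def test_constant_map_epsilon_guard(self):
        cfg = LossConfig(theta=0.5, omega=100.0)
        amap = AttentionMap(values=np.full((3, 3), 7.0))
        sm = soft_mask(amap, (3, 3), cfg)
        expected = 1.0 / (1.0 + math.exp(100.0 * 0.5))
        np.testing.assert_allclose(sm.values, expected, atol=1e-12)

    def test_sharpening_limit(self, rng):
        # omega -> inf converges to the indicator of {hbar > theta}
        cfg = LossConfig(theta=0.5, omega=1e4)
        vals = rng.choice([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], size=(6, 6))
        vals.flat[0] = 0.0
        vals.flat[1] = 1.0  # pin the min-max range
        sm = soft_mask(AttentionMap(values=vals), (6, 6), cfg)
        indicator = (vals > 0.5).astype(float)
        assert np.abs(sm.values - indicator).max() < 1e-6

    def test_upsamples_to_label_shape(self, rng):
        sm = soft_mask(AttentionMap(values=rng.normal(size=(4, 5))), (16, 20),
                       LossConfig())
        assert sm.values.shape == (16, 20)

    def test_values_in_unit_interval(self, rng):
        sm = soft_mask(AttentionMap(values=rng.normal(size=(5, 5))), (10, 10),
                       LossConfig())
        assert sm.values.min() >= 0.0 and sm.values.max() <= 1.0


class TestSoftIoU:
    def test_identical_binary_masks(self):
        y = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert soft_iou(SoftMask(values=y.copy()), y) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        h = np.array([[1.0, 0.0], [0.0, 0.0]])
        y = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert soft_iou(SoftMask(values=h), y) == pytest.approx(0.0)

    def test_2x2_pixel_counting_example(self):
        h = np.array([[1.0, 1.0], [0.0, 0.0]])
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert soft_iou(SoftMask(values=h), y) == pytest.approx(1.0 / 3.0)

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            soft_iou(SoftMask(values=np.ones((2, 2))), np.zeros((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            soft_iou(SoftMask(values=np.ones((2, 2))), np.ones((3, 3)))

    def test_nonbinary_label_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            soft_iou(SoftMask(values=np.ones((2, 2))), np.full((2, 2), 0.5))

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_binary_agreement_with_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        shape = (int(r.integers(1, 17)), int(r.integers(1, 17)))
        h = r.integers(0, 2, size=shape).astype(float)
        y = r.integers(0, 2, size=shape).astype(float)
        if y.sum() == 0:
            y.flat[0] = 1.0
        got = soft_iou(SoftMask(values=h), y)
        assert got == pytest.approx(_pixel_iou(h, y), abs=1e-12)

    def test_minmax_mode_agrees_on_binary(self, rng):
        h = rng.integers(0, 2, size=(8, 8)).astype(float)
        y = rng.integers(0, 2, size=(8, 8)).astype(float)
        y.flat[0] = 1.0
        assert soft_iou(SoftMask(values=h), y, mode="minmax") == pytest.approx(
            _pixel_iou(h, y)
        )

    def test_monotonicity_inside_and_outside(self, rng):
        y = np.zeros((6, 6))
        y[2:5, 2:5] = 1.0
        h = rng.uniform(0.05, 0.95, size=(6, 6))
        base = soft_iou(SoftMask(values=h), y)
        inside = h.copy()
        inside[3, 3] = min(1.0, inside[3, 3] + 0.04)
        assert soft_iou(SoftMask(values=inside), y) >= base
        outside = h.copy()
        outside[0, 0] = min(1.0, outside[0, 0] + 0.04)
        assert soft_iou(SoftMask(values=outside), y) <= base


class TestAttentionLoss:
    def test_absent_label_is_zero(self):
        assert attention_loss(None, None) == 0.0

    def test_perfect_overlap_is_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert attention_loss(SoftMask(values=y.copy()), y) == pytest.approx(0.0)

    def test_2x2_example(self):
        h = np.array([[1.0, 1.0], [0.0, 0.0]])
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert attention_loss(SoftMask(values=h), y) == pytest.approx(2.0 / 3.0)

    def test_label_without_mask_errors(self):
        with pytest.raises(ValueError):
            attention_loss(None, np.ones((2, 2)))

    def test_range(self, rng):
        for _ in range(20):
            h = rng.uniform(size=(5, 5))
            y = rng.integers(0, 2, size=(5, 5)).astype(float)
            y.flat[0] = 1.0
            val = attention_loss(SoftMask(values=h), y)
            assert 0.0 <= val <= 1.0


class TestClassificationLoss:
    def test_uniform_logits_log3(self):
        scores = ClassScores(logits=np.zeros(3))
        assert classification_loss(scores, 0) == pytest.approx(math.log(3), abs=1e-12)

    def test_saturated_softmax(self):
        scores = ClassScores(logits=np.array([100.0, 0.0, 0.0]))
        assert classification_loss(scores, 0) == pytest.approx(0.0, abs=1e-10)

    def test_direct_evaluation_oracle(self):
        z = np.array([1.0, 2.0, 3.0])
        # independent oracle: plain softmax arithmetic
        expected = -math.log(math.exp(3) / sum(math.exp(v) for v in z))
        got = classification_loss(ClassScores(logits=z), 2)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.40761, abs=1e-5)

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            classification_loss(ClassScores(logits=np.zeros(3)), 3)

    def test_nonnegative(self, rng):
        for _ in range(20):
            z = rng.normal(scale=5, size=4)
            assert classification_loss(ClassScores(logits=z), 1) >= 0.0

    def test_stable_for_large_logits(self):
        z = np.array([1e4, 1e4 - 5.0])
        got = classification_loss(ClassScores(logits=z), 0)
        assert got == pytest.approx(math.log(1 + math.exp(-5.0)), abs=1e-10)


class TestTotalLoss:
    def test_zero(self):
        assert total_loss(0.0, 0.0, LossConfig()) == 0.0

    def test_default_weights_example(self):
        assert total_loss(1.0, 0.5, LossConfig()) == pytest.approx(2.5)

    def test_unlabeled_sample_reduces_to_classification(self):
        cfg = LossConfig()
        l_cls = 0.7
        assert total_loss(l_cls, attention_loss(None, None), cfg) == pytest.approx(
            cfg.alpha_cls * l_cls
        )


class TestDifferentiability:
    def test_attention_loss_gradient_matches_finite_difference(self, rng):
        """Central finite differences vs autodiff on a 3x4x4 toy stack."""
        maps = rng.normal(size=(3, 4, 4))
        weights = rng.normal(size=3)
        y = np.zeros((8, 8))
        y[2:5, 2:6] = 1.0
        cfg = LossConfig(omega=20.0, gradcam_relu=False)

        def loss(m):
            t = ad.Tensor(m, requires_grad=True)
            h = ad.tsum(t * weights[:, None, None], axis=0)
            sm = soft_mask(AttentionMap(values=h), y.shape, cfg)
            return t, attention_loss(sm, y)

        t, out = loss(maps)
        out.backward()
        eps = 1e-6
        for idx in [(0, 1, 2), (1, 3, 0), (2, 2, 2), (0, 0, 0), (2, 3, 3)]:
            mp = maps.copy()
            mp[idx] += eps
            mm = maps.copy()
            mm[idx] -= eps
            fd = (loss(mp)[1].item() - loss(mm)[1].item()) / (2 * eps)
            assert t.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestLossConfig:
    @pytest.mark.parametrize(
        "kw", [{"theta": 1.2}, {"omega": 0}, {"alpha_cls": -1}, {"epsilon": 0},
               {"iou_mode": "fancy"}]
    )
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValueError):
            LossConfig(**kw)

    def test_defaults(self):
        cfg = LossConfig()
        assert cfg.theta == 0.5
        assert cfg.omega == 100.0
        assert (cfg.alpha_cls, cfg.alpha_att) == (2.0, 1.0)
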