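"""CWCE loss identities, augmentation operators, stain round-trips,
gradient-accumulation equivalence, and model architecture contracts."""

import math

import numpy as np
import pytest

from histocascade import _nn as nn
from histocascade.errors import ConfigError
from histocascade.models import (
    ClassifierSpec,
    RefinerSpec,
    build_patch_classifier,
    build_refiner,
    load_model,
    save_model,
)
from histocascade.train import (
    AugmentConfig,
    PredictionBatch,
    augment_patch,
    augment_seg_pair,
    cwce_loss,
    estimate_stain_matrix,
    macenko_stain_augment,
    soft_dice_loss,
)

NO_AUG = AugmentConfig(operators=())


class TestCwceLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        q = np.array([0, 0])
        assert cwce_loss(PredictionBatch(probs, y, q)) == pytest.approx(
            0.0, abs=1e-6)

    def test_single_cluster_reduces_to_mean_cross_entropy(self):
        probs = np.array([[0.5, 0.5], [0.5, 0.5]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        q = np.array([3, 3])
        loss = cwce_loss(PredictionBatch(probs, y, q))
        assert loss == pytest.approx(math.log(2), rel=1e-9)

    def test_two_cluster_macro_average_worked_example(self):
        """Cluster A: one sample with CE 0; cluster B: one with CE 1 ->
        macro average 0.5."""
        probs = np.array([[1.0, 0.0], [math.exp(-1), 1 - math.exp(-1)]])
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        q = np.array([0, 1])
        assert cwce_loss(PredictionBatch(probs, y, q)) == pytest.approx(
            0.5, rel=1e-6)

    def test_macro_not_sample_weighted(self):
        """99 CE-1 samples in cluster B still average against one CE-0
        sample in cluster A: loss stays 0.5."""
        pA = np.array([[1.0, 0.0]])
        pB = np.tile([math.exp(-1), 1 - math.exp(-1)], (99, 1))
        probs = np.vstack([pA, pB])
        y = np.tile([1.0, 0.0], (100, 1))
        q = np.array([0] + [1] * 99)
        assert cwce_loss(PredictionBatch(probs, y, q)) == pytest.approx(
            0.5, rel=1e-6)

    def test_within_cluster_duplication_invariance(self, rng):
        probs = rng.dirichlet([1, 1], size=6)
        y = np.eye(2)[rng.integers(0, 2, 6)]
        q = np.array([0, 0, 1, 1, 2, 2])
        base = cwce_loss(PredictionBatch(probs, y, q))
        dup = cwce_loss(PredictionBatch(
            np.vstack([probs, probs[2:4]]), np.vstack([y, y[2:4]]),
            np.concatenate([q, [1, 1]])))
        assert dup == pytest.approx(base, rel=1e-9)

    def test_batch_order_permutation_invariance(self, rng):
        probs = rng.dirichlet([1, 1], size=8)
        y = np.eye(2)[rng.integers(0, 2, 8)]
        q = rng.integers(0, 3, 8)
        perm = rng.permutation(8)
        a = cwce_loss(PredictionBatch(probs, y, q))
        b = cwce_loss(PredictionBatch(probs[perm], y[perm], q[perm]))
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_probability_clipped_not_nan(self):
        probs = np.array([[0.0, 1.0]])
        y = np.array([[1.0, 0.0]])
        loss = cwce_loss(PredictionBatch(probs, y, np.array([0])))
        assert math.isfinite(loss)
        assert loss == pytest.approx(-math.log(1e-7), rel=1e-6)


class TestAugmentPatch:
    def test_noop_config_is_identity(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        cfg = AugmentConfig(operators=("hsv", "brightness"),
                            hsv_shift=(0, 0), brightness=(1.0, 1.0))
        out = augment_patch(img, np.random.default_rng(0), cfg)
        assert np.allclose(out, img, atol=1e-5)

    def test_flip_preserves_value_multiset(self, rng):
        img = rng.random((16, 16, 3)).astype(np.float32)
        cfg = AugmentConfig(operators=("flip", "rot90"))
        out = augment_patch(img, np.random.default_rng(1), cfg)
        assert np.allclose(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_output_range_and_determinism(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        cfg = AugmentConfig()
        a = augment_patch(img, np.random.default_rng(7), cfg)
        b = augment_patch(img, np.random.default_rng(7), cfg)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0

    def test_four_rot90_identity(self, rng):
        img = rng.random((8, 8, 3)).astype(np.float32)
        out = img
        for _ in range(4):
            out = np.rot90(out, 1)
        assert np.array_equal(out, img)


class TestMacenko:
    @staticmethod
    def _two_dye_image(rng, angles_deg=(20.0, 70.0)):
        """Synthesize an image from two known unit stain vectors."""
        t = np.deg2rad(np.asarray(angles_deg))
        # stain vectors in a 2D OD plane embedded in RGB OD space
        basis = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        basis /= np.linalg.norm(basis, axis=0)
        stains = basis @ np.stack([np.cos(t), np.sin(t)])  # 3 x 2
        stains /= np.linalg.norm(stains, axis=0)
        conc = rng.uniform(0.2, 1.2, size=(2, 4096))
        od = (stains @ conc).T.reshape(64, 64, 3)
        return np.power(10.0, -od).astype(np.float32), stains

    def test_zero_sigma_identity(self, rng):
        img, _ = self._two_dye_image(np.random.default_rng(0))
        out = macenko_stain_augment(img, np.random.default_rng(1), 0.0, 0.0)
        assert np.abs(out - img).max() < 2.0 / 255.0

    def test_pure_white_unchanged(self):
        img = np.ones((32, 32, 3), dtype=np.float32)
        out = macenko_stain_augment(img, np.random.default_rng(2))
        assert np.array_equal(out, img)

    def test_seeded_determinism(self, rng):
        img, _ = self._two_dye_image(np.random.default_rng(3))
        a = macenko_stain_augment(img, np.random.default_rng(5))
        b = macenko_stain_augment(img, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_estimated_stains_bracket_generating_angles(self):
        img, stains = self._two_dye_image(np.random.default_rng(4))
        he = estimate_stain_matrix(img)
        assert he is not None
        # each estimated stain vector aligns with one generating vector,
        # and the best matches form a bijection (the extremes bracket the
        # wedge rather than collapsing onto one side)
        cos = np.abs(he.T @ stains)  # 2x2 alignment matrix
        assert np.all(cos.max(axis=1) > 0.98)
        assert cos[0].argmax() != cos[1].argmax()

    def test_nonzero_sigma_perturbs_tissue(self):
        img, _ = self._two_dye_image(np.random.default_rng(6))
        out = macenko_stain_augment(img, np.random.default_rng(7), 0.3, 0.0)
        assert np.abs(out - img).max() > 0.01


class TestAugmentSegPair:
    def _triplet(self, rng):
        img = rng.random((64, 64, 3)).astype(np.float32)
        hm = rng.random((64, 64)).astype(np.float32)
        gt = (rng.random((64, 64)) > 0.5).astype(np.float32)
        return img, hm, gt

    def test_cotransform_flip(self, rng):
        img, hm, gt = self._triplet(rng)
        cfg = AugmentConfig(operators=("flip",), p_apply=1.0)
        # p_apply=1 forces both flips: hflip then vflip
        oi, oh, og = augment_seg_pair(img, hm, gt, np.random.default_rng(0),
                                      cfg)
        assert np.array_equal(oi, img[::-1, ::-1])
        assert np.array_equal(oh, hm[::-1, ::-1])
        assert np.array_equal(og, gt[::-1, ::-1])

    def test_zoom_one_identity(self, rng):
        img, hm, gt = self._triplet(rng)
        cfg = AugmentConfig(operators=("zoom",), zoom=(1.0, 1.0), p_apply=1.0)
        oi, oh, og = augment_seg_pair(img, hm, gt, np.random.default_rng(1),
                                      cfg)
        assert np.allclose(oi, img, atol=1e-6)
        assert np.array_equal(og, gt)

    def test_zoom_in_matches_resize_crop_oracle(self, rng):
        from skimage.transform import resize

        img, hm, gt = self._triplet(rng)
        cfg = AugmentConfig(operators=("zoom",), zoom=(1.2, 1.2), p_apply=1.0)
        oi, _, _ = augment_seg_pair(img, hm, gt, np.random.default_rng(2),
                                    cfg)
        big = resize(img.astype(np.float64), (77, 77, 3), order=1,
                     anti_aliasing=False, preserve_range=True, mode="edge")
        y0 = (77 - 64) // 2
        oracle = big[y0:y0 + 64, y0:y0 + 64]
        assert np.abs(oi - oracle).max() < 1e-4

    def test_shape_mismatch_raises(self, rng):
        from histocascade.errors import GeometryError

        img, hm, gt = self._triplet(rng)
        with pytest.raises(GeometryError):
            augment_seg_pair(img, hm[:32], gt, np.random.default_rng(0),
                             AugmentConfig())


class TestSoftDice:
    def test_gradient_matches_finite_differences(self, rng):
        p = rng.random((2, 6, 6)).astype(np.float64)
        t = (rng.random((2, 6, 6)) > 0.5).astype(np.float64)
        loss, grad = soft_dice_loss(p, t)
        eps = 1e-6
        for idx in [(0, 1, 2), (1, 3, 3), (0, 5, 5)]:
            pp = p.copy()
            pp[idx] += eps
            lp, _ = soft_dice_loss(pp, t)
            pp[idx] -= 2 * eps
            lm, _ = soft_dice_loss(pp, t)
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-3)

    def test_perfect_overlap_near_zero(self):
        t = np.zeros((1, 8, 8))
        t[0, 2:6, 2:6] = 1
        loss, _ = soft_dice_loss(t.copy(), t)
        assert loss < 0.05


class TestArchitectures:
    def test_classifier_softmax_contract(self, rng):
        clf = build_patch_classifier()
        p = clf.predict_proba(rng.random((3, 256, 256, 3)).astype(np.float32))
        assert p.shape == (3, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_head_introspection(self):
        clf = build_patch_classifier()
        assert clf.head_description() == [
            "global_average_pool", "dense(100)", "dropout(0.5)", "relu",
            "batch_norm", "dense(2)+softmax",
        ]

    def test_three_class_head(self, rng):
        clf = build_patch_classifier(ClassifierSpec(n_classes=3))
        p = clf.predict_proba(rng.random((2, 256, 256, 3)).astype(np.float32))
        assert p.shape == (2, 3)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigError):
            build_patch_classifier(ClassifierSpec(backbone_id="resnet9000"))

    def test_default_refiner_spec_is_full_scale(self):
        spec = RefinerSpec()
        assert spec.depth == 9
        assert spec.filters == (8, 16, 32, 64, 128, 128, 256, 256, 512)
        assert spec.input_size == 1024
        spec.validate()

    def test_reduced_refiner_builds_and_runs(self, rng):
        spec = RefinerSpec(input_size=64, depth=4, filters=(4, 8, 8, 16))
        ref = build_refiner(spec)
        p = ref.forward_probs(rng.random((2, 64, 64, 4)).astype(np.float32))
        assert p.shape == (2, 64, 64, 2)
        assert np.abs(p.sum(axis=-1) - 1).max() < 1e-5

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigError):
            build_refiner(RefinerSpec(input_size=100, depth=4,
                                      filters=(4, 8, 8, 16)))

    def test_model_serialization_roundtrip(self, tmp_path, rng):
        spec = RefinerSpec(input_size=32, depth=3, filters=(4, 8, 8))
        ref = build_refiner(spec)
        x = rng.random((1, 32, 32, 4)).astype(np.float32)
        before = ref.forward_probs(x)
        save_model(ref, tmp_path / "r.bin")
        loaded = load_model(tmp_path / "r.bin")
        assert np.array_equal(loaded.forward_probs(x), before)


class TestGradientAccumulation:
    def test_accumulated_step_equals_full_batch_step(self, rng):
        """Six accumulated micro-batches of 4 produce the same gradients
        (and hence the same Adam step) as one batch of 24, with batch norm
        in inference mode."""
        spec = RefinerSpec(input_size=32, depth=3, filters=(4, 8, 8), seed=3)
        x = rng.random((24, 32, 32, 4)).astype(np.float32)
        t = (rng.random((24, 32, 32)) > 0.5).astype(np.float32)

        def grads(micro_size):
            model = build_refiner(spec)
            for p in model.params():
                p.grad[...] = 0
            n_micro = 24 // micro_size
            for i in range(n_micro):
                sl = slice(i * micro_size, (i + 1) * micro_size)
                probs = model.forward_probs(x[sl], train=False)
                _, dfg = soft_dice_loss(probs[..., 1], t[sl])
                dprobs = np.zeros_like(probs)
                dprobs[..., 1] = dfg / n_micro
                model.backward_probs(dprobs.astype(np.float32))
            return [p.grad.copy() for p in model.params()]

        g_full = grads(24)
        g_acc = grads(4)
        for a, b in zip(g_full, g_acc):
            denom = np.abs(a).max() + 1e-8
            assert np.abs(a - b).max() / denom < 5e-4
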