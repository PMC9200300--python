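"""Encoder-decoder segmenter: gradients, losses, training, TTA."""

import math

import numpy as np
import pytest

from mpquant.imaging_core import FluorescenceImage
from mpquant.segnet import (
    ModelConfig,
    adjust_brightness,
    adjust_contrast,
    bce_logits_loss,
    build_model,
    cross_validate,
    dice_bce_loss,
    dice_loss,
    default_tta_augmentations,
    loss_and_grad,
    predict_mask,
    shift_hsv,
    sigmoid,
    train,
    tta_predict,
)


def tiny_config(**kw):
    defaults = dict(depth=1, base_width=4, loss="dice", optimizer="sgd",
                    batch_size=2, epochs=3, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestBuildModel:
    def test_shape_contract(self):
        model = build_model(tiny_config())
        x = np.zeros((2, 3, 64, 64), np.float32)
        assert model.forward(x).shape == (2, 1, 64, 64)

    def test_same_seed_identical_parameters(self):
        m1 = build_model(tiny_config(seed=9))
        m2 = build_model(tiny_config(seed=9))
        for (n1, v1, _), (n2, v2, _) in zip(m1.parameters(), m2.parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(v1, v2)

    def test_wider_model_has_strictly_more_parameters(self):
        small = build_model(tiny_config(base_width=4))
        wide = build_model(tiny_config(base_width=8))
        assert wide.n_parameters() > small.n_parameters()

    def test_indivisible_patch_size_rejected(self):
        model = build_model(tiny_config(depth=2))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 3, 10, 10), np.float32))

    def test_save_load_roundtrip(self, tmp_path):
        model = build_model(tiny_config(seed=4))
        model.save(tmp_path / "m.npz")
        from mpquant.segnet import UNet

        back = UNet.load(tmp_path / "m.npz")
        x = np.random.default_rng(0).random((1, 3, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), back.forward(x))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences (float64)."""
        model = build_model(tiny_config(depth=2, base_width=2, seed=3))
        for conv in model._conv_layers():
            for k in conv.params:
                conv.params[k] = conv.params[k].astype(np.float64)
                conv.grads[k] = conv.grads[k].astype(np.float64)
        rng = np.random.default_rng(0)
        x = rng.random((2, 3, 8, 8))
        t = (rng.random((2, 1, 8, 8)) > 0.7).astype(np.float64)

        loss, dl = loss_and_grad("dice_bce", model.forward(x), t)
        model.zero_grad()
        model.backward(dl.astype(np.float64))
        eps = 1e-6
        for conv in model._conv_layers():
            for key in ("w", "b"):
                flat = conv.params[key].ravel()
                grad = conv.grads[key].ravel()
                for i in rng.integers(0, flat.size, size=min(3, flat.size)):
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp = loss_and_grad("dice_bce", model.forward(x), t)[0]
                    flat[i] = orig - eps
                    lm = loss_and_grad("dice_bce", model.forward(x), t)[0]
                    flat[i] = orig
                    num = (lp - lm) / (2 * eps)
                    assert grad[i] == pytest.approx(num, rel=5e-3, abs=1e-7)


class TestLosses:
    def test_dice_perfect_prediction_near_zero(self, rng):
        t = (rng.random((16, 16)) > 0.7).astype(float)
        area = t.sum()
        loss = dice_loss(t, t)
        assert loss <= 1.0 / (2 * area + 1.0)

    def test_dice_disjoint_near_one(self):
        p = np.zeros((8, 8))
        t = np.zeros((8, 8))
        p[:4] = 1.0
        t[4:] = 1.0
        a = 32
        assert dice_loss(p, t) == pytest.approx(1 - 1 / (2 * a + 1))

    def test_dice_half_overlap_is_half_in_large_area_limit(self):
        n = 200
        p = np.zeros((n, n))
        t = np.zeros((n, n))
        p[:, : n // 2] = 1.0  # area a
        t[:, n // 4 : 3 * n // 4] = 1.0  # area a, half overlapping
        assert dice_loss(p, t) == pytest.approx(0.5, abs=1e-4)

    def test_dice_range(self, rng):
        p = rng.random((10, 10))
        t = (rng.random((10, 10)) > 0.5).astype(float)
        assert 0.0 <= dice_loss(p, t) <= 1.0

    def test_bce_saturated_logit_near_zero(self):
        z = np.full((4, 4), 100.0)
        t = np.ones((4, 4))
        assert bce_logits_loss(z, t) == pytest.approx(0.0, abs=1e-6)

    def test_bce_zero_logits_is_log2(self):
        z = np.zeros((4, 4))
        t = (np.arange(16).reshape(4, 4) % 2).astype(float)
        assert bce_logits_loss(z, t) == pytest.approx(math.log(2))

    def test_bce_matches_naive_formula_at_moderate_logits(self, rng):
        z = rng.normal(0, 3, (6, 6))
        t = (rng.random((6, 6)) > 0.5).astype(float)
        p = 1 / (1 + np.exp(-z))
        naive = float(np.mean(-(t * np.log(p) + (1 - t) * np.log(1 - p))))
        assert bce_logits_loss(z, t) == pytest.approx(naive, abs=1e-6)

    def test_dice_bce_is_sum(self, rng):
        z = rng.normal(0, 2, (5, 5))
        t = (rng.random((5, 5)) > 0.5).astype(float)
        assert dice_bce_loss(z, t) == pytest.approx(
            dice_loss(sigmoid(z), t) + bce_logits_loss(z, t)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestTraining:
    def _patch_set(self, n=12, size=16, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 40, (n, size, size, 3), dtype=np.uint8)
        Y = np.zeros((n, size, size), np.uint8)
        for i in range(n):
            r, c = rng.integers(3, size - 6, 2)
            X[i, r : r + 4, c : c + 4] = 230
            Y[i, r : r + 4, c : c + 4] = 1
        return X, Y

    def test_loss_decreases(self):
        X, Y = self._patch_set()
        cfg = tiny_config(depth=2, base_width=4, epochs=15, batch_size=4)
        model = build_model(cfg)
        model, curves = train(model, X, Y, config=cfg)
        assert curves.train_loss[-1] < curves.train_loss[0]

    def test_two_runs_same_seed_identical(self):
        X, Y = self._patch_set()
        cfg = tiny_config(depth=1, base_width=4, epochs=3, batch_size=4, seed=2)
        _, c1 = train(build_model(cfg), X, Y, config=cfg)
        _, c2 = train(build_model(cfg), X, Y, config=cfg)
        assert c1.train_loss == c2.train_loss

    def test_empty_training_set_rejected(self):
        cfg = tiny_config()
        with pytest.raises(ValueError):
            train(build_model(cfg), np.zeros((0, 16, 16, 3)), np.zeros((0, 16, 16)),
                  config=cfg)

    def test_validation_selects_best_epoch(self):
        X, Y = self._patch_set(n=8)
        Xv, Yv = self._patch_set(n=4, seed=5)
        cfg = tiny_config(depth=1, base_width=4, epochs=5, batch_size=4)
        model, curves = train(build_model(cfg), X, Y, Xv, Yv, config=cfg)
        assert 1 <= curves.best_epoch <= 5
        assert len(curves.val_loss) == 5


class TestPrediction:
    def test_fresh_head_zeroed_model_gives_half_probability_empty_mask(self):
        model = build_model(tiny_config())
        # zero every parameter: logits identically 0 -> p = 0.5 exactly
        for _, value, _ in model.parameters():
            value[...] = 0.0
        img = FluorescenceImage(
            pixels=np.random.default_rng(1).integers(0, 255, (32, 32, 3),
                                                     dtype=np.uint8)
        )
        prob, mask = predict_mask(model, img, patch_size=16)
        np.testing.assert_allclose(prob, 0.5)
        assert mask.foreground_count == 0  # strict > 0.5

    def test_output_shapes_match_input(self):
        model = build_model(tiny_config(depth=2, base_width=4))
        img = FluorescenceImage(
            pixels=np.zeros((50, 70, 3), np.uint8)
        )
        prob, mask = predict_mask(model, img, patch_size=32)
        assert prob.shape == (50, 70)
        assert mask.shape == (50, 70)

    def test_overfit_single_scene_high_iou(self):
        from mpquant.evaluate import confusion, metrics
        from mpquant.synthio import default_scene_sampler, generate_scene

        sampler = default_scene_sampler(canvas=(64, 64), n_objects_range=(2, 3),
                                        size_range=(8, 14))
        img, mask, _ = generate_scene(sampler(np.random.default_rng(5), 0))
        cfg = ModelConfig(depth=2, base_width=8, loss="dice", optimizer="adam",
                          epochs=250, batch_size=1, seed=1)
        model = build_model(cfg)
        model, _ = train(model, img.pixels[None], mask.pixels[None], config=cfg)
        _, pred = predict_mask(model, img, patch_size=64)
        assert metrics(confusion(pred, mask)).iou > 0.9


class TestTTA:
    def _model_and_image(self):
        model = build_model(tiny_config(seed=3))
        img = FluorescenceImage(
            pixels=np.random.default_rng(2).integers(0, 255, (32, 32, 3),
                                                     dtype=np.uint8)
        )
        return model, img

    def test_identity_augmentations_match_plain_prediction(self):
        model, img = self._model_and_image()
        plain, _ = predict_mask(model, img, patch_size=16)
        tta, _ = tta_predict(model, img, [lambda x: x, lambda x: x], patch_size=16)
        np.testing.assert_allclose(tta, plain)

    def test_empty_augmentation_list_is_plain_prediction(self):
        model, img = self._model_and_image()
        plain, _ = predict_mask(model, img, patch_size=16)
        tta, _ = tta_predict(model, img, [], patch_size=16)
        np.testing.assert_allclose(tta, plain)

    def test_average_bounded_by_individual_maps(self):
        model, img = self._model_and_image()
        augs = default_tta_augmentations()
        maps = [predict_mask(model, img, patch_size=16)[0]]
        for aug in augs:
            aug_img = FluorescenceImage(pixels=aug(img.pixels))
            maps.append(predict_mask(model, aug_img, patch_size=16)[0])
        combined, _ = tta_predict(model, img, augs, patch_size=16)
        lo = np.min(maps, axis=0)
        hi = np.max(maps, axis=0)
        assert (combined >= lo - 1e-12).all() and (combined <= hi + 1e-12).all()
        assert combined.shape == (32, 32)
        assert combined.min() >= 0 and combined.max() <= 1


class TestAugmentOps:
    def test_identity_parameters(self, random_image):
        px = random_image.pixels
        np.testing.assert_array_equal(adjust_brightness(px, 0), px)
        np.testing.assert_array_equal(shift_hsv(px, 0, 0, 0), px)

    def test_contrast_factor_one_is_identity(self, random_image):
        px = random_image.pixels
        np.testing.assert_allclose(
            adjust_contrast(px, 1.0).astype(int), px.astype(int), atol=1
        )

    def test_brightness_clips_at_255(self):
        px = np.full((4, 4, 3), 240, np.uint8)
        assert (adjust_brightness(px, 25) == 255).all()

    def test_hue_full_turn_is_identity_within_rounding(self, random_image):
        out = shift_hsv(random_image.pixels, dh=360.0)
        assert np.abs(out.astype(int) - random_image.pixels.astype(int)).max() <= 1


class TestCrossValidate:
    def test_identical_folds_identical_means(self):
        from mpquant.evaluate import confusion, metrics
        from mpquant.synthio import default_scene_sampler, generate_scene

        sampler = default_scene_sampler(canvas=(32, 32), n_objects_range=(1, 2),
                                        size_range=(8, 10))
        img, mask, _ = generate_scene(sampler(np.random.default_rng(3), 0))
        X = img.pixels[None]
        Y = mask.pixels[None]
        fold_data = {f"cvf{i}": (X, Y) for i in range(1, 5)}
        cfg = tiny_config(depth=1, base_width=4, epochs=2, batch_size=1)

        def metric_fn(pred, truth):
            return metrics(confusion(pred, truth)).as_dict()

        models, report = cross_validate(fold_data, [(img, mask)], cfg, metric_fn,
                                        stride=32)
        assert len(models) == 4
        assert len(report) == 5  # 4 runs + mean row
        ious = report[report["run"] != "mean"]["iou"]
        assert ious.nunique() == 1  # identical folds -> identical results
        mean_row = report[report["run"] == "mean"].iloc[0]
        assert mean_row["iou"] == pytest.approx(ious.mean())

    def test_missing_fold_rejected(self):
        cfg = tiny_config()
        with pytest.raises(ValueError, match="cvf4"):
            cross_validate({"cvf1": (None, None)}, [], cfg, lambda p, t: {})
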