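"""Desk-scale reference experiments on synthetic scenes.

The headline comparison — a trained encoder-decoder segmenter against
entropy thresholding — is reproduced here as a scaled-down surrogate: 30
synthetic scenes with halos and dark cores (the two artefacts that defeat
global thresholding), a tiny network (depth 2, width 8, Dice + SGD)
trained for 30 epochs on 200 MP-containing 32x32 patches from 20 scenes,
and evaluated on the 10 held-out scenes against the max-entropy pipeline.

Problem sizes are chosen so the whole study runs in about a minute on one
CPU core while preserving the qualitative ordering of the full-scale
comparison.
"""

from __future__ import annotations

import numpy as np

from .evaluate import confusion, metrics
from .patchwork import extract_patches, filter_empty_patches
from .segnet import ModelConfig, build_model, predict_mask, train
from .synthio import default_scene_sampler, generate_scene
from .thresholding import ThresholdModelSpec, run_tr_model

__all__ = ["segmentation_ordering_experiment"]

#: study conditions: halo and dark-core severity of the evaluation scenes
HALO_STRENGTH = 0.6
DARK_CORE_FRACTION = 0.5


def segmentation_ordering_experiment(
    seed: int,
    n_scenes: int = 30,
    n_train_scenes: int = 20,
    n_patches: int = 200,
    patch_size: int = 32,
    patch_stride: int = 16,
    epochs: int = 30,
) -> dict:
    """Train a tiny segmenter and compare it with mp_vat on held-out scenes.

    Returns a dict with the per-method mean IoU on the held-out scenes, the
    final training loss, and the problem sizes used.  Fully deterministic
    given ``seed``.
    """
    sampler = default_scene_sampler(
        halo_strength=HALO_STRENGTH, dark_core_fraction=DARK_CORE_FRACTION
    )
    rng = np.random.default_rng(seed)
    scenes = [generate_scene(sampler(rng, i)) for i in range(n_scenes)]
    train_scenes = scenes[:n_train_scenes]
    test_scenes = scenes[n_train_scenes:]

    xs, ys = [], []
    for image, mask, _ in train_scenes:
        _, ip = extract_patches(image.pixels, size=patch_size, stride=patch_stride)
        _, mp = extract_patches(mask.pixels, size=patch_size, stride=patch_stride)
        ipf, mpf = filter_empty_patches(list(ip), list(mp))
        xs += ipf
        ys += mpf
    pick = np.random.default_rng(seed + 1).permutation(len(xs))[:n_patches]
    X = np.stack([xs[i] for i in pick])
    Y = np.stack([ys[i] for i in pick])

    config = ModelConfig(
        depth=2, base_width=8, loss="dice", optimizer="sgd",
        epochs=epochs, batch_size=8, seed=seed,
    )
    model = build_model(config)
    model, curves = train(model, X, Y, config=config)

    vat_spec = ThresholdModelSpec.preset("mp_vat")
    net_ious, vat_ious = [], []
    for image, mask, _ in test_scenes:
        _, pred = predict_mask(model, image, patch_size=patch_size)
        net_ious.append(metrics(confusion(pred, mask)).iou)
        vat_ious.append(metrics(confusion(run_tr_model(image, vat_spec), mask)).iou)

    return {
        "net_mean_iou": float(np.mean(net_ious)),
        "mp_vat_mean_iou": float(np.mean(vat_ious)),
        "final_train_loss": float(curves.train_loss[-1]),
        "n_train_patches": int(len(X)),
        "n_test_scenes": len(test_scenes),
    }
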