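"""Training, cross-validation, and patch-based full-image prediction.

Images are tiled into fixed-size patches; the network is trained on
(patch, mask-patch) pairs by seeded mini-batch gradient descent, and
full-image prediction tiles the input, runs every patch through the
network, merges the sigmoid probabilities (mean over overlaps) and
thresholds strictly at a probability cutoff (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ..imaging_core import BinaryMask, FluorescenceImage
from ..patchwork import extract_patches, merge_patches
from .losses import dice_loss, loss_and_grad, sigmoid
from .model import ModelConfig, UNet, build_model
from .optim import clip_grad_norm, make_optimizer

__all__ = [
    "TrainingCurves",
    "train",
    "cross_validate",
    "predict_patches",
    "predict_mask",
    "tta_predict",
]


@dataclass
class TrainingCurves:
    """Per-epoch training history."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": [v if v == v else np.nan for v in self.val_loss],
                "val_iou": self.val_iou,
            }
        )


def _as_batches(x: np.ndarray) -> np.ndarray:
    """uint8 patch stack (N,H,W,3) -> float32 NCHW in [0, 1]."""
    x = np.asarray(x, dtype=np.float32) / 255.0
    return x.transpose(0, 3, 1, 2)


def _mask_batch(y: np.ndarray) -> np.ndarray:
    return np.asarray(y, dtype=np.float32)[:, None, :, :]


def _soft_iou(prob: np.ndarray, target: np.ndarray) -> float:
    pred = prob > 0.5
    t = target > 0.5
    union = np.logical_or(pred, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, t).sum() / union)


def train(
    model: UNet,
    train_images: np.ndarray,
    train_masks: np.ndarray,
    val_images: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
    config: ModelConfig | None = None,
) -> tuple[UNet, TrainingCurves]:
    """Seeded mini-batch training; returns the best-validation-epoch model.

    ``train_images`` is a uint8 stack (N, H, W, 3); ``train_masks`` a
    binary stack (N, H, W).  Without a validation set the final epoch's
    parameters are kept.  Fully deterministic given the config seed.
    """
    config = config or model.config
    if len(train_images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed + 1)
    opt = make_optimizer(model, config)
    curves = TrainingCurves()

    x_all = _as_batches(train_images)
    y_all = _mask_batch(train_masks)
    has_val = val_images is not None and len(val_images) > 0
    if has_val:
        xv = _as_batches(val_images)
        yv = _mask_batch(val_masks)

    best_state = None
    best_val = np.inf
    n = len(x_all)
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits = model.forward(x_all[idx])
            loss, dlogits = loss_and_grad(config.loss, logits, y_all[idx])
            model.zero_grad()
            model.backward(dlogits)
            if config.max_grad_norm is not None:
                clip_grad_norm(model, config.max_grad_norm)
            opt.step()
            losses.append(loss)
        curves.train_loss.append(float(np.mean(losses)))

        if has_val:
            probs = _forward_probs(model, xv, bs)
            vloss = dice_loss(probs, yv)
            viou = _soft_iou(probs, yv)
            curves.val_loss.append(float(vloss))
            curves.val_iou.append(viou)
            if vloss < best_val:
                best_val = vloss
                best_state = model.get_state()
                curves.best_epoch = epoch + 1
        else:
            curves.val_loss.append(float("nan"))
            curves.val_iou.append(float("nan"))
            curves.best_epoch = epoch + 1

    if best_state is not None:
        model.set_state(best_state)
    return model, curves


def _forward_probs(model: UNet, x: np.ndarray, batch_size: int) -> np.ndarray:
    chunks = [
        sigmoid(model.forward(x[i : i + batch_size]))
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(chunks, axis=0)


def cross_validate(
    fold_data: Mapping[str, tuple[np.ndarray, np.ndarray]],
    test_data: Sequence[tuple[FluorescenceImage, BinaryMask]],
    config: ModelConfig,
    metric_fn: Callable[[BinaryMask, BinaryMask], Mapping[str, float]],
    stride: int | None = None,
) -> tuple[list[UNet], pd.DataFrame]:
    """4-fold cross-validated training with a fixed test set.

    ``fold_data`` maps ``cvf1..cvf4`` to (patch, mask-patch) stacks.  Run k
    trains on three folds and validates on the remaining one (run 1
    validates on CVF4, run 2 on CVF3, ...).  Every fine-tuned model is
    scored on the test images; the report has one row per run plus a
    ``mean`` row — the grand mean of the four fold means.
    """
    folds = ["cvf1", "cvf2", "cvf3", "cvf4"]
    if set(folds) - set(fold_data):
        raise ValueError(f"missing folds: {sorted(set(folds) - set(fold_data))}")
    models = []
    rows = []
    for k in range(4):
        val_fold = folds[3 - k]
        train_folds = [f for f in folds if f != val_fold]
        xt = np.concatenate([fold_data[f][0] for f in train_folds])
        yt = np.concatenate([fold_data[f][1] for f in train_folds])
        xv, yv = fold_data[val_fold]
        model = build_model(config)
        model, _ = train(model, xt, yt, xv, yv, config)
        models.append(model)
        per_image = []
        for image, truth in test_data:
            _, pred = predict_mask(model, image, stride=stride)
            per_image.append(dict(metric_fn(pred, truth)))
        fold_mean = {
            key: float(np.mean([m[key] for m in per_image])) for key in per_image[0]
        }
        rows.append({"run": f"fine_tuning_{k + 1}", "val_fold": val_fold, **fold_mean})
    report = pd.DataFrame(rows)
    metric_cols = [c for c in report.columns if c not in ("run", "val_fold")]
    grand = {c: float(report[c].mean()) for c in metric_cols}
    report = pd.concat(
        [report, pd.DataFrame([{"run": "mean", "val_fold": "", **grand}])],
        ignore_index=True,
    )
    return models, report


def predict_patches(
    model: UNet, image: FluorescenceImage, stride: int | None = None,
    patch_size: int | None = None, batch_size: int = 8,
):
    """Tile an image, predict per-patch probabilities, and return both."""
    size = patch_size or _native_patch_size(model, image)
    grid, patches = extract_patches(image.pixels, size=size, stride=stride or size)
    probs = _forward_probs(model, _as_batches(patches), batch_size)[:, 0]
    return grid, probs


def _native_patch_size(model: UNet, image: FluorescenceImage) -> int:
    # largest power-of-two-compatible window up to 256 that fits the model
    mult = 2**model.config.depth
    size = min(256, max(image.shape[0], image.shape[1]))
    return max(mult, (size // mult) * mult)


def predict_mask(
    model: UNet,
    image: FluorescenceImage,
    threshold: float = 0.5,
    stride: int | None = None,
    patch_size: int | None = None,
) -> tuple[np.ndarray, BinaryMask]:
    """Full-image prediction: (probability map, binary mask).

    The mask is ``probability > threshold`` (strict, so an exactly-0.5 map
    under the default cutoff is background).
    """
    grid, probs = predict_patches(model, image, stride=stride, patch_size=patch_size)
    prob_map = merge_patches(grid, probs)
    return prob_map, BinaryMask(pixels=(prob_map > threshold).astype(np.uint8))


def tta_predict(
    model: UNet,
    image: FluorescenceImage,
    augmentations: Sequence[Callable[[np.ndarray], np.ndarray]],
    threshold: float = 0.5,
    stride: int | None = None,
    patch_size: int | None = None,
) -> tuple[np.ndarray, BinaryMask]:
    """Test-time augmentation: average probabilities over the original
    image and each photometrically augmented copy, then threshold.

    With an empty augmentation list this is plain :func:`predict_mask`.
    """
    maps = [predict_mask(model, image, stride=stride, patch_size=patch_size)[0]]
    for aug in augmentations:
        augmented = FluorescenceImage(
            pixels=aug(image.pixels), scale=image.scale, id=image.id
        )
        maps.append(
            predict_mask(model, augmented, stride=stride, patch_size=patch_size)[0]
        )
    prob_map = np.mean(maps, axis=0)
    return prob_map, BinaryMask(pixels=(prob_map > threshold).astype(np.uint8))
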