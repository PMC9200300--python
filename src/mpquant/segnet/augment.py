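"""Photometric augmentations for test-time augmentation (TTA).

All transforms act on 8-bit RGB arrays, clip to [0, 255], and leave
geometry untouched, so their "inverse" on a probability map is the
identity — TTA reduces to pixel-wise averaging of predictions.  Default
magnitudes: brightness +/-25, contrast x0.8 / x1.2, hue shift +/-10
degrees.
"""

from __future__ import annotations

import numpy as np
from skimage import color

__all__ = [
    "adjust_brightness",
    "adjust_contrast",
    "shift_hsv",
    "default_tta_augmentations",
]


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def adjust_brightness(image: np.ndarray, delta: float) -> np.ndarray:
    """Add ``delta`` intensity units to every channel."""
    return _to_uint8(image.astype(np.float64) + delta)


def adjust_contrast(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale contrast about the image mean: ``mean + factor * (x - mean)``."""
    x = image.astype(np.float64)
    mean = x.mean()
    return _to_uint8(mean + factor * (x - mean))


def shift_hsv(
    image: np.ndarray, dh: float = 0.0, ds: float = 0.0, dv: float = 0.0
) -> np.ndarray:
    """Shift hue (degrees, wrapped), saturation and value (in [0,1] units)."""
    hsv = color.rgb2hsv(image.astype(np.float64) / 255.0)
    hsv[:, :, 0] = (hsv[:, :, 0] + dh / 360.0) % 1.0
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] + ds, 0.0, 1.0)
    hsv[:, :, 2] = np.clip(hsv[:, :, 2] + dv, 0.0, 1.0)
    return _to_uint8(color.hsv2rgb(hsv) * 255.0)


def default_tta_augmentations(
    brightness_delta: float = 25.0,
    contrast_factors: tuple[float, float] = (0.8, 1.2),
    hue_delta: float = 10.0,
):
    """The default TTA set: brightness up/down, contrast down/up, hue +/-."""
    return [
        lambda im: adjust_brightness(im, +brightness_delta),
        lambda im: adjust_brightness(im, -brightness_delta),
        lambda im: adjust_contrast(im, contrast_factors[0]),
        lambda im: adjust_contrast(im, contrast_factors[1]),
        lambda im: shift_hsv(im, dh=+hue_delta),
        lambda im: shift_hsv(im, dh=-hue_delta),
    ]
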