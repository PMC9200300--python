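"""Domain types and image/mask I/O shared by every stage.

The whole pipeline is built around three rasters:

* :class:`FluorescenceImage` — an 8-bit RGB microscopy image ``I`` of shape
  ``(h, w, 3)``, optionally carrying a physical scale in µm per pixel.
* :class:`IntensityImage` — a single-channel 8-bit image ``G`` obtained by
  channel reduction (grayscale luminance or the red channel).
* :class:`BinaryMask` — the per-pixel microplastic (MP) / background
  labelling.  Internally foreground is always ``1`` and background ``0``;
  the 255/0 and black-on-white conventions found in mask files are handled
  at (de)serialization time through an explicit polarity flag.

Coordinates are row-major, origin top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "FluorescenceImage",
    "IntensityImage",
    "BinaryMask",
    "Histogram",
    "ITU_R_601_WEIGHTS",
    "read_image",
    "read_mask",
    "write_mask",
    "to_gray",
    "red_channel",
    "histogram",
]

#: ITU-R 601 luminance weights (R, G, B) — the convention of the ImageJ-style
#: tooling this package is benchmarked against.  Overridable in :func:`to_gray`.
ITU_R_601_WEIGHTS: tuple[float, float, float] = (0.299, 0.587, 0.114)


@dataclass
class FluorescenceImage:
    """An 8-bit RGB fluorescence microscopy image with optional µm/px scale."""

    pixels: np.ndarray
    scale: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (h, w, 3) raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have h >= 1 and w >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class IntensityImage:
    """A single-channel 8-bit intensity image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected (h, w) raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensity values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Per-pixel MP/background labelling; foreground (MP) is 1, background 0."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected (h, w) mask, got shape {px.shape}")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class Histogram:
    """256-bin intensity histogram with normalized frequencies ``q``."""

    counts: np.ndarray
    q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValueError("histogram must have exactly 256 bins")
        if (c < 0).any():
            raise ValueError("histogram counts must be non-negative")
        self.counts = c
        total = c.sum()
        self.q = c / total if total > 0 else np.zeros(256)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def read_image(
    path: str | Path,
    *,
    scale: float | None = None,
    rescale_16bit: bool = False,
) -> FluorescenceImage:
    """Read a PNG/TIFF/JPEG file as an 8-bit RGB :class:`FluorescenceImage`.

    Grayscale files are promoted to three identical channels.  16-bit TIFFs
    are accepted only with ``rescale_16bit=True``, in which case values are
    mapped onto [0, 255] by max-normalization (``round(v * 255 / max)``).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"cannot decode image file {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        if not rescale_16bit:
            raise ValueError(
                f"{path} has bit depth > 8; pass rescale_16bit=True to max-normalize"
            )
        arr = arr.astype(np.int64)
        peak = int(arr.max())
        if peak > 0:
            # integer round-half-up of v * 255 / peak
            arr = (arr * 255 * 2 + peak) // (2 * peak)
        arr = arr.astype(np.uint8)

    if arr.ndim == 2:
        arr = np.stack([arr, arr, arr], axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] != 3:
        raise IOError(f"{path}: unsupported channel count {arr.shape[2]}")
    return FluorescenceImage(pixels=arr, scale=scale, id=path.stem)


def write_mask(mask: BinaryMask, path: str | Path, polarity: str = "mp_white") -> None:
    """Serialize a mask as an 8-bit PNG.

    ``mp_white`` writes foreground as 255 on black; ``mp_black`` writes
    foreground as 0 on white (the display convention of hand-annotated
    masks, where MP pieces are drawn black on a white page).
    """
    arr = _polarize(mask.pixels, polarity)
    iio.imwrite(Path(path), arr)


def read_mask(path: str | Path, polarity: str = "mp_white") -> BinaryMask:
    """Read an 8-bit mask file back into the internal 1/0 convention."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read mask: no such file {path}")
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    fg = arr >= 128
    if polarity == "mp_black":
        fg = ~fg
    elif polarity != "mp_white":
        raise ValueError(f"unknown polarity {polarity!r}")
    return BinaryMask(pixels=fg.astype(np.uint8))


def _polarize(px: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "mp_white":
        return (px * 255).astype(np.uint8)
    if polarity == "mp_black":
        return ((1 - px) * 255).astype(np.uint8)
    raise ValueError(f"unknown polarity {polarity!r}")


def to_gray(
    image: FluorescenceImage,
    weights: Sequence[float] = ITU_R_601_WEIGHTS,
) -> IntensityImage:
    """Reduce RGB to luminance (weighted sum, rounded to 8-bit)."""
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,):
        raise ValueError("need exactly three luminance weights")
    lum = image.pixels.astype(np.float64) @ w
    return IntensityImage(pixels=np.clip(np.rint(lum), 0, 255).astype(np.uint8))


def red_channel(image: FluorescenceImage) -> IntensityImage:
    """Extract the red channel unchanged (Nile red fluoresces red-dominant)."""
    return IntensityImage(pixels=image.pixels[:, :, 0].copy())


def histogram(intensity: IntensityImage) -> Histogram:
    """256-bin histogram of an intensity image."""
    px = intensity.pixels
    if px.size == 0:
        raise ValueError("cannot histogram an empty raster")
    counts = np.bincount(px.ravel(), minlength=256)
    return Histogram(counts=counts)
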