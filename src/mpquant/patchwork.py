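"""Dataset preparation: fold assignment, patch extraction, patch merging.

Whole micrographs are too large (and too variably sized) for a fixed-input
network, so images are tiled into fixed-size square patches with a sliding
window, and patch predictions are merged back by averaging overlaps.

Cross-validation splits are balanced by MP content with a serpentine deal:
images sorted by ascending MP-pixel count are dealt in the repeating order
``test, CVF1, CVF2, CVF3, CVF4, CVF4, CVF3, CVF2, CVF1, test`` so no split
ends up systematically MP-richer than another.  With 99 images this yields
a 19-image test set and four 20-image folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatchGrid",
    "FoldAssignment",
    "SPLITS",
    "assign_folds",
    "extract_patches",
    "filter_empty_patches",
    "subsample_empty_patches",
    "merge_patches",
]

SPLITS = ("test", "cvf1", "cvf2", "cvf3", "cvf4")
_SERPENTINE = ("test", "cvf1", "cvf2", "cvf3", "cvf4",
               "cvf4", "cvf3", "cvf2", "cvf1", "test")


@dataclass(frozen=True)
class PatchGrid:
    """Window layout tiling one image; origins are top-left (row, col)."""

    patch_size: int
    stride: int
    origins: tuple[tuple[int, int], ...]
    padded_shape: tuple[int, int]
    original_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return len(self.origins)


@dataclass(frozen=True)
class FoldAssignment:
    """Per-image split labels; every image belongs to exactly one split."""

    labels: dict[str, str]  # image id -> split

    def ids(self, split: str) -> list[str]:
        return [i for i, s in self.labels.items() if s == split]

    def sizes(self) -> dict[str, int]:
        return {s: len(self.ids(s)) for s in SPLITS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"id": i, "split": s} for i, s in self.labels.items()],
            columns=["id", "split"],
        )


def assign_folds(mp_pixel_counts: Mapping[str, int]) -> FoldAssignment:
    """Serpentine-deal images into test + 4 cross-validation folds.

    Images are sorted by ascending MP-pixel count (ties broken by id) and
    dealt in the order test,1,2,3,4,4,3,2,1,test repeatedly.  Deterministic.
    """
    if not mp_pixel_counts:
        raise ValueError("need at least one image")
    order = sorted(mp_pixel_counts, key=lambda i: (mp_pixel_counts[i], i))
    labels = {img: _SERPENTINE[k % 10] for k, img in enumerate(order)}
    return FoldAssignment(labels=labels)


def _grid_axis(dim: int, stride: int) -> int:
    return max(1, -(-dim // stride))  # ceil(dim / stride), >= 1


def extract_patches(
    array: np.ndarray, size: int = 256, stride: int | None = None
) -> tuple[PatchGrid, np.ndarray]:
    """Tile a 2-D (or channels-last 3-D) array into size x size windows.

    The input is zero-padded on the bottom/right so each of the
    ``ceil(dim / stride)`` window origins per axis carries a full window.
    Returns the grid and an array of patches, ordered row-major by origin.
    """
    stride = size if stride is None else stride
    if size < 1 or not 1 <= stride <= size:
        raise ValueError("need size >= 1 and 1 <= stride <= size")
    h, w = array.shape[:2]
    nr, nc = _grid_axis(h, stride), _grid_axis(w, stride)
    ph, pw = (nr - 1) * stride + size, (nc - 1) * stride + size
    pad = [(0, ph - h), (0, pw - w)] + [(0, 0)] * (array.ndim - 2)
    padded = np.pad(array, pad)
    origins = tuple(
        (r * stride, c * stride) for r in range(nr) for c in range(nc)
    )
    patches = np.stack(
        [padded[r : r + size, c : c + size] for r, c in origins]
    )
    grid = PatchGrid(
        patch_size=size,
        stride=stride,
        origins=origins,
        padded_shape=(ph, pw),
        original_shape=(h, w),
    )
    return grid, patches


def filter_empty_patches(
    image_patches: Sequence[np.ndarray], mask_patches: Sequence[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Keep only pairs whose mask patch contains at least one MP pixel."""
    if len(image_patches) != len(mask_patches):
        raise ValueError("image/mask patch lists differ in length")
    keep = [i for i, m in enumerate(mask_patches) if np.any(np.asarray(m) > 0)]
    return [image_patches[i] for i in keep], [mask_patches[i] for i in keep]


def subsample_empty_patches(
    image_patches: Sequence[np.ndarray],
    mask_patches: Sequence[np.ndarray],
    max_empty_ratio: float,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Randomly delete excess MP-free patches down to a target ratio.

    Keeps all MP-containing pairs and at most
    ``max_empty_ratio * n_nonempty`` seeded-random empty ones.
    """
    if len(image_patches) != len(mask_patches):
        raise ValueError("image/mask patch lists differ in length")
    nonempty = [i for i, m in enumerate(mask_patches) if np.any(np.asarray(m) > 0)]
    empty = [i for i in range(len(mask_patches)) if i not in set(nonempty)]
    n_keep = int(max_empty_ratio * len(nonempty))
    rng = np.random.default_rng(seed)
    kept_empty = sorted(
        rng.choice(empty, size=min(n_keep, len(empty)), replace=False).tolist()
    )
    keep = sorted(nonempty + kept_empty)
    return [image_patches[i] for i in keep], [mask_patches[i] for i in keep]


def merge_patches(grid: PatchGrid, patch_values: np.ndarray) -> np.ndarray:
    """Reassemble per-patch maps into a full-size map.

    Overlapping pixels take the arithmetic mean of every contributing
    window; bottom/right padding is cropped away.  The inverse of
    :func:`extract_patches` when stride = size.
    """
    patch_values = np.asarray(patch_values, dtype=np.float64)
    if patch_values.shape[0] != grid.n_patches:
        raise ValueError(
            f"expected {grid.n_patches} patches, got {patch_values.shape[0]}"
        )
    s = grid.patch_size
    acc = np.zeros(grid.padded_shape)
    cnt = np.zeros(grid.padded_shape)
    for (r, c), patch in zip(grid.origins, patch_values):
        acc[r : r + s, c : c + s] += patch
        cnt[r : r + s, c : c + s] += 1.0
    merged = acc / cnt
    h, w = grid.original_shape
    return merged[:h, :w]
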