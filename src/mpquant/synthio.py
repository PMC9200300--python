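"""Synthetic Nile-red-style fluorescence scene generator.

Real Nile-red micrographs are dark, noisy filter-paper backgrounds with
bright red-dominant fluorescent objects.  Three shape archetypes occur:
near-circular *particles*, irregular *fragments*, and elongated *fibers* —
matching the circularity bands used downstream for shape classification
(fiber < 0.3, fragment 0.3–0.6, particle >= 0.6).

Two imaging artefacts matter because they are exactly what defeats global
thresholding and motivates learned segmentation:

* **halos** — a fluorescence glow around very bright objects.  Halos are
  rendered into the IMAGE but not the ground-truth MASK, so a thresholder
  that picks them up commits false positives (Type 1 errors);
* **dark cores** — thick particles photograph dark in the middle.  Cores
  darken the image inside the mask, so a thresholder loses them (Type 2
  errors / false negatives).

Every scene is fully determined by its :class:`SceneSpec` (including the
seed): same spec in, bit-identical image/mask/table out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .imaging_core import BinaryMask, FluorescenceImage, write_mask
import imageio.v3 as iio

__all__ = [
    "ObjectSpec",
    "SceneSpec",
    "generate_scene",
    "generate_dataset",
    "default_scene_sampler",
]

#: RGB weights of the fluorescent signal (red-dominant, as under a
#: Nile-red filter set)
_OBJECT_RGB = (1.0, 0.72, 0.30)


@dataclass(frozen=True)
class ObjectSpec:
    """One rendered MP piece.

    ``size`` is the characteristic length in pixels: diameter for particles
    and fragments, arc length for fibers.  ``irregularity`` in [0, 1]
    controls boundary perturbation for fragments and waviness for fibers.
    """

    archetype: str  # particle | fragment | fiber
    center: tuple[float, float]  # (row, col)
    size: float
    orientation: float = 0.0
    brightness: int = 230
    irregularity: float = 0.5

    def __post_init__(self) -> None:
        if self.archetype not in ("particle", "fragment", "fiber"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not 0 <= self.brightness <= 255:
            raise ValueError("brightness must be 8-bit")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; the seed fixes every sample."""

    canvas: tuple[int, int] = (128, 128)
    objects: tuple[ObjectSpec, ...] = ()
    background_level: float = 20.0
    background_noise_sd: float = 5.0
    halo_strength: float = 0.0  # [0, 1]
    dark_core_fraction: float = 0.0  # fraction of objects given a dark core
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "objects", tuple(self.objects))


def _render_particle(obj: ObjectSpec, shape, rng) -> np.ndarray:
    # ellipse with eccentricity < 0.3 -> minor/major > 0.954
    a = max(obj.size / 2.0, 1.0)
    b = a * (0.955 + 0.045 * (1.0 - obj.irregularity))
    fp = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.ellipse(
        obj.center[0], obj.center[1], a, b,
        shape=shape, rotation=obj.orientation,
    )
    fp[rr, cc] = True
    return fp


def _render_fragment(obj: ObjectSpec, shape, rng) -> np.ndarray:
    # spiky polygon: vertex radii alternate between the full and a reduced
    # radius, pushing circularity into the fragment band
    n = 10
    R = max(obj.size / 2.0, 2.0)
    ang = obj.orientation + np.linspace(0, 2 * math.pi, n, endpoint=False)
    lo = 0.35 + 0.2 * (1.0 - obj.irregularity)
    radii = np.where(
        np.arange(n) % 2 == 0,
        R,
        R * (lo + 0.1 * rng.random(n)),
    )
    rows = obj.center[0] + radii * np.sin(ang)
    cols = obj.center[1] + radii * np.cos(ang)
    fp = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.polygon(rows, cols, shape=shape)
    fp[rr, cc] = True
    return fp


def _render_fiber(obj: ObjectSpec, shape, rng) -> np.ndarray:
    # thickened random-walk polyline; width (1-3 px) is capped well below the
    # arc length so circularity ~ pi*width/length stays in the fiber band
    n_steps = max(int(obj.size), 12)
    heading = obj.orientation
    r, c = obj.center
    rows, cols = [r], [c]
    for _ in range(n_steps):
        heading += (rng.random() - 0.5) * obj.irregularity * 0.9
        r += math.sin(heading)
        c += math.cos(heading)
        rows.append(r)
        cols.append(c)
    fp = np.zeros(shape, dtype=bool)
    for i in range(len(rows) - 1):
        rr, cc = skdraw.line(
            int(round(rows[i])), int(round(cols[i])),
            int(round(rows[i + 1])), int(round(cols[i + 1])),
        )
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        fp[rr[keep], cc[keep]] = True
    width = 1 + int(rng.integers(0, min(2, int(obj.size) // 24) + 1))
    if width >= 2:  # one-pixel smear down/right
        fp = fp | np.roll(fp, 1, axis=0) | np.roll(fp, 1, axis=1)
    if width == 3:
        fp = ndimage.binary_dilation(fp)
    return fp


_RENDERERS: dict[str, Callable] = {
    "particle": _render_particle,
    "fragment": _render_fragment,
    "fiber": _render_fiber,
}


def _footprint(obj: ObjectSpec, shape, rng) -> np.ndarray:
    return _RENDERERS[obj.archetype](obj, shape, rng)


def generate_scene(spec: SceneSpec) -> tuple[FluorescenceImage, BinaryMask, pd.DataFrame]:
    """Render a scene: (image, ground-truth mask, per-object table).

    The mask foreground is the union of the rendered object footprints.
    Halos and dark cores perturb only the image.  Objects whose nominal
    extent does not fit the canvas raise an error naming the object index.
    """
    h, w = spec.canvas
    rng = np.random.default_rng(spec.seed)

    for i, obj in enumerate(spec.objects):
        r, c = obj.center
        half = obj.size / 2.0
        if obj.archetype == "fiber":
            half = max(obj.size, 14)  # a walk can extend up to its arc length
        if r - half < -1 or c - half < -1 or r + half > h or c + half > w:
            raise ValueError(f"object {i} ({obj.archetype}) does not fit the canvas")

    # clipped Gaussian noise: real dark backgrounds have a compact, hard-edged
    # intensity mode (black-level clamp), not a long sparse tail
    img = np.clip(
        rng.normal(spec.background_level, spec.background_noise_sd, (h, w)),
        spec.background_level - 2 * spec.background_noise_sd,
        spec.background_level + 2 * spec.background_noise_sd,
    )
    mask = np.zeros((h, w), dtype=np.uint8)
    records = []
    signal = np.zeros((h, w))

    for i, obj in enumerate(spec.objects):
        fp = _footprint(obj, (h, w), rng)
        area = int(fp.sum())
        mask[fp] = 1
        # slight per-pixel texture on the object body
        body = obj.brightness * (0.92 + 0.08 * rng.random((h, w)))
        signal = np.where(fp, np.maximum(signal, body), signal)

        if spec.dark_core_fraction > 0 and rng.random() < spec.dark_core_fraction:
            core = ndimage.binary_erosion(fp, iterations=max(1, int(obj.size / 5)))
            if core.any():
                signal[core] = spec.background_level + 10.0

        records.append(
            {
                "index": i,
                "archetype": obj.archetype,
                "area_px2": area,
                "center_row": obj.center[0],
                "center_col": obj.center[1],
                "size": obj.size,
                "brightness": obj.brightness,
            }
        )

    if spec.halo_strength > 0 and mask.any():
        glow = ndimage.gaussian_filter((mask > 0).astype(float), sigma=3.0)
        halo = spec.halo_strength * 255.0 * glow
        img = np.where(mask == 0, np.maximum(img, halo), img)

    img = np.maximum(img, np.where(mask > 0, signal, 0.0))
    rgb = np.stack([np.clip(img * wgt, 0, 255) for wgt in _OBJECT_RGB], axis=-1)
    # background is neutral gray noise; objects are red-dominant
    bg = np.clip(img, 0, 255)
    obj_or_halo = (mask > 0) | (rgb[:, :, 0] > spec.background_level + 4 * spec.background_noise_sd)
    for ch in range(3):
        rgb[:, :, ch] = np.where(obj_or_halo, rgb[:, :, ch], bg)
    image = FluorescenceImage(
        pixels=np.rint(rgb).astype(np.uint8), id=f"scene_{spec.seed}"
    )
    table = pd.DataFrame.from_records(
        records,
        columns=["index", "archetype", "area_px2", "center_row", "center_col",
                 "size", "brightness"],
    )
    return image, BinaryMask(pixels=mask), table


def default_scene_sampler(
    canvas: tuple[int, int] = (128, 128),
    n_objects_range: tuple[int, int] = (3, 8),
    size_range: tuple[float, float] = (8.0, 22.0),
    brightness_range: tuple[int, int] = (200, 255),
    background_level: float = 20.0,
    background_noise_sd: float = 5.0,
    halo_strength: float = 0.0,
    dark_core_fraction: float = 0.0,
    min_separation: float = 6.0,
    archetypes: tuple[str, ...] = ("particle", "fragment", "fiber"),
) -> Callable[[np.random.Generator, int], SceneSpec]:
    """Build a sampler of random :class:`SceneSpec`s for dataset generation.

    Object centers are drawn by rejection sampling so footprints stay
    disjoint (separation >= object radii sum + ``min_separation``) and fit
    inside the canvas.
    """
    h, w = canvas

    def sample(rng: np.random.Generator, index: int) -> SceneSpec:
        n = int(rng.integers(n_objects_range[0], n_objects_range[1] + 1))
        objs: list[ObjectSpec] = []
        placed: list[tuple[float, float, float]] = []  # row, col, reach
        attempts = 0
        while len(objs) < n and attempts < 2000:
            attempts += 1
            archetype = archetypes[int(rng.integers(len(archetypes)))]
            size = float(rng.uniform(*size_range))
            reach = max(size, 14) if archetype == "fiber" else size / 2.0
            margin = reach + 2
            if 2 * margin >= min(h, w):
                continue
            r = float(rng.uniform(margin, h - margin))
            c = float(rng.uniform(margin, w - margin))
            if any(
                math.hypot(r - pr, c - pc) < reach + pre + min_separation
                for pr, pc, pre in placed
            ):
                continue
            objs.append(
                ObjectSpec(
                    archetype=archetype,
                    center=(r, c),
                    size=size,
                    orientation=float(rng.uniform(0, 2 * math.pi)),
                    brightness=int(rng.integers(*brightness_range)),
                    irregularity=float(rng.uniform(0.4, 0.9)),
                )
            )
            placed.append((r, c, reach))
        return SceneSpec(
            canvas=canvas,
            objects=tuple(objs),
            background_level=background_level,
            background_noise_sd=background_noise_sd,
            halo_strength=halo_strength,
            dark_core_fraction=dark_core_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    return sample


def generate_dataset(
    n_images: int,
    out_dir: str | Path,
    sampler: Callable[[np.random.Generator, int], SceneSpec] | None = None,
    seed: int = 0,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write ``n_images`` image/mask PNG pairs plus a manifest CSV.

    Manifest columns: ``id, n_objects, mp_pixels, seed``.  Filenames are
    deterministic (``scene_000.png`` / ``scene_000_mask.png``).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} is not empty")
    out_dir.mkdir(parents=True, exist_ok=True)

    sampler = sampler or default_scene_sampler()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_images):
        spec = sampler(rng, i)
        image, mask, table = generate_scene(spec)
        sid = f"scene_{i:03d}"
        iio.imwrite(out_dir / f"{sid}.png", image.pixels)
        write_mask(mask, out_dir / f"{sid}_mask.png", polarity="mp_white")
        rows.append(
            {
                "id": sid,
                "n_objects": len(spec.objects),
                "mp_pixels": mask.foreground_count,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=["id", "n_objects", "mp_pixels", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
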