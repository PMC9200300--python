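"""Object-level quantification: counting, shape classification, sizing.

Given a binary mask, connected foreground components (8-connectivity) are
the individual MP pieces.  Each piece is measured:

* area — pixel count (µm² when a physical scale is set);
* perimeter — Crofton-formula contour-length estimate (4 directions),
  which is asymptotically unbiased on smooth shapes (a digital disk of
  radius 50 measures within a fraction of a percent of ``2*pi*r``);
* circularity — ``4 * pi * area / perimeter**2`` clamped to [0, 1];
* Feret diameter — the longest straight line drawable within the piece,
  computed as the maximum pairwise distance over the convex hull of the
  pixel *corner* points (so even a single pixel has Feret sqrt(2));
* shape class — fiber (circularity < 0.3), fragment ([0.3, 0.6)) or
  particle (>= 0.6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure

from .imaging_core import BinaryMask

__all__ = [
    "MPObject",
    "QuantSummary",
    "label_components",
    "measure_object",
    "classify_shape",
    "quantify_mask",
]

_EIGHT = np.ones((3, 3), dtype=int)
SHAPE_CLASSES = ("fiber", "fragment", "particle")


@dataclass
class MPObject:
    """One connected MP piece and its morphometry."""

    label: int
    area: int
    perimeter: float
    circularity: float
    feret: float
    centroid: tuple[float, float]
    shape_class: str
    area_um2: float | None = None
    feret_um: float | None = None


@dataclass
class QuantSummary:
    """Per-image tabulated MP summary."""

    image_id: str
    objects: list[MPObject] = field(default_factory=list)

    @property
    def mp_count(self) -> int:
        return len(self.objects)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in SHAPE_CLASSES}
        for obj in self.objects:
            counts[obj.shape_class] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": self.image_id,
                "label": o.label,
                "area_px2": o.area,
                "area_um2": o.area_um2,
                "perimeter_px": o.perimeter,
                "circularity": o.circularity,
                "feret_px": o.feret,
                "feret_um": o.feret_um,
                "shape_class": o.shape_class,
            }
            for o in self.objects
        ]
        return pd.DataFrame(
            rows,
            columns=["id", "label", "area_px2", "area_um2", "perimeter_px",
                     "circularity", "feret_px", "feret_um", "shape_class"],
        )


def label_components(mask: BinaryMask) -> tuple[np.ndarray, int]:
    """8-connected component labelling, labels 1..K in raster-scan order."""
    labelled, n = ndimage.label(mask.pixels, structure=_EIGHT)
    return labelled, int(n)


def classify_shape(circularity: float) -> str:
    """Map circularity to fiber / fragment / particle.

    Band boundaries 0.3 and 0.6 assign upward (fragment, particle); 1.0 is
    a particle.
    """
    if not 0.0 <= circularity <= 1.0:
        raise ValueError(f"circularity {circularity} outside [0, 1]")
    if circularity < 0.3:
        return "fiber"
    if circularity < 0.6:
        return "fragment"
    return "particle"


def _feret_diameter(rows: np.ndarray, cols: np.ndarray) -> float:
    # corners of each pixel: (r, c), (r, c+1), (r+1, c), (r+1, c+1)
    pts = np.concatenate(
        [
            np.stack([rows, cols], axis=1),
            np.stack([rows, cols + 1], axis=1),
            np.stack([rows + 1, cols], axis=1),
            np.stack([rows + 1, cols + 1], axis=1),
        ]
    ).astype(np.float64)
    pts = np.unique(pts, axis=0)
    hull_pts = pts[ConvexHull(pts).vertices]
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def measure_object(
    component: np.ndarray, label: int = 1, scale: float | None = None
) -> MPObject:
    """Measure one connected component given as a boolean raster."""
    comp = np.asarray(component, dtype=bool)
    rows, cols = np.nonzero(comp)
    if rows.size == 0:
        raise ValueError("cannot measure an empty component")
    area = int(rows.size)
    perimeter = float(skmeasure.perimeter_crofton(comp, directions=4))
    if perimeter > 0:
        circ = min(1.0, 4.0 * math.pi * area / perimeter**2)
    else:  # single pixel or degenerate contour: maximally compact
        circ = 1.0
    feret = _feret_diameter(rows, cols)
    return MPObject(
        label=label,
        area=area,
        perimeter=perimeter,
        circularity=circ,
        feret=feret,
        centroid=(float(rows.mean()), float(cols.mean())),
        shape_class=classify_shape(circ),
        area_um2=area * scale**2 if scale else None,
        feret_um=feret * scale if scale else None,
    )


def quantify_mask(
    mask: BinaryMask,
    scale: float | None = None,
    image_id: str = "",
    min_area: int = 0,
) -> QuantSummary:
    """Label, measure and classify every MP piece in a mask.

    ``min_area`` (default 0 = off) drops components below a pixel-area
    floor before measurement.
    """
    labelled, n = label_components(mask)
    summary = QuantSummary(image_id=image_id)
    out_label = 0
    for lab in range(1, n + 1):
        comp = labelled == lab
        if min_area and comp.sum() < min_area:
            continue
        out_label += 1
        summary.objects.append(measure_object(comp, label=out_label, scale=scale))
    return summary
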