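"""Classical global-thresholding segmenters for fluorescent MP images.

Four published tool families share the same two-step structure: a channel
reduction ``f_{I->G}`` followed by a global threshold ``f_{G->M}``:

========== ============== =========================================
model      channel        threshold rule
========== ============== =========================================
custom     gray           user-supplied fixed T
mp_vat     gray           Kapur maximum-entropy
mp_vat2    red            Rényi entropy (Sahoo three-alpha weighting)
c_vat      gray           fixed T = 222, with despeckle + outlier removal
========== ============== =========================================

The binarization rule is strict: a pixel is MP iff its intensity is
strictly greater than T.  Entropy computations use natural logarithms;
the threshold argmax is base-invariant, so this choice is observationally
irrelevant and recorded only for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_core import (
    BinaryMask,
    FluorescenceImage,
    Histogram,
    IntensityImage,
    histogram,
    red_channel,
    to_gray,
)

__all__ = [
    "ThresholdModelSpec",
    "binarize",
    "renyi_entropy",
    "shannon_entropy",
    "max_entropy_threshold",
    "renyi_threshold",
    "despeckle",
    "remove_outliers",
    "run_tr_model",
]

#: absolute threshold of the C-VAT workflow
C_VAT_FIXED_T = 222


@dataclass
class ThresholdModelSpec:
    """Configuration of one thresholding segmenter.

    ``name`` selects a preset wiring; ``fixed_value`` is required for the
    ``custom`` rule.  C-VAT's despeckle/outlier parameters are not published
    for the original tool, so ``outlier_min_size`` (default 4 px²) is
    config-exposed and a documented divergence risk.
    """

    name: str = "custom"
    channel: str = "gray"
    threshold_rule: str = "fixed"
    fixed_value: int | None = None
    preprocess: list[str] = field(default_factory=list)
    postprocess: list[str] = field(default_factory=list)
    outlier_min_size: int = 4

    @classmethod
    def preset(cls, name: str, fixed_value: int | None = None) -> "ThresholdModelSpec":
        name = name.replace("-", "_")
        if name == "mp_vat":
            return cls(name="mp_vat", channel="gray", threshold_rule="max_entropy")
        if name == "mp_vat2":
            return cls(name="mp_vat2", channel="red", threshold_rule="renyi")
        if name == "c_vat":
            return cls(
                name="c_vat",
                channel="gray",
                threshold_rule="fixed",
                fixed_value=C_VAT_FIXED_T,
                preprocess=["despeckle"],
                postprocess=["remove_outliers"],
            )
        if name == "custom":
            return cls(name="custom", channel="gray", threshold_rule="fixed",
                       fixed_value=fixed_value)
        raise ValueError(f"unknown threshold model {name!r}")


def binarize(intensity: IntensityImage, T: int) -> BinaryMask:
    """Global threshold: foreground iff value > T (strict)."""
    if not 0 <= T <= 255:
        raise ValueError(f"threshold {T} outside [0, 255]")
    return BinaryMask(pixels=(intensity.pixels > T).astype(np.uint8))


def renyi_entropy(q: np.ndarray, alpha: float) -> float:
    """Rényi entropy ``H_a = 1/(1-a) * log(sum_k q_k^a)`` (natural log).

    Zero-probability bins contribute nothing.  ``alpha`` must be positive
    and different from 1 (use :func:`shannon_entropy` for the a -> 1 limit).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha == 1:
        raise ValueError("alpha = 1 is the Shannon limit; use shannon_entropy")
    q = np.asarray(q, dtype=np.float64)
    s = float(np.sum(q[q > 0] ** alpha))
    return math.log(s) / (1.0 - alpha)


def shannon_entropy(q: np.ndarray) -> float:
    """Shannon entropy ``-sum q log q`` (the alpha -> 1 limit of Rényi)."""
    q = np.asarray(q, dtype=np.float64)
    pos = q[q > 0]
    return float(-np.sum(pos * np.log(pos)))


def _class_criterion_shannon(q: np.ndarray) -> np.ndarray:
    """Kapur criterion H(<=T) + H(>T) for every candidate T in 0..255.

    Splits leaving either class empty score -inf.  Uses the identity
    H(class) = log P - (1/P) * sum q log q over the class.
    """
    qlogq = np.where(q > 0, q * np.log(np.where(q > 0, q, 1.0)), 0.0)
    P = np.cumsum(q)
    S = np.cumsum(qlogq)
    crit = np.full(256, -np.inf)
    for t in range(256):
        pb, pf = P[t], 1.0 - P[t]
        if pb <= 0 or pf <= 0:
            continue
        hb = math.log(pb) - S[t] / pb
        hf = math.log(pf) - (S[255] - S[t]) / pf
        crit[t] = hb + hf
    return crit


def _class_criterion_renyi(q: np.ndarray, alpha: float) -> np.ndarray:
    """Two-class Rényi criterion for every candidate T in 0..255."""
    qa = np.where(q > 0, q, 0.0) ** alpha
    P = np.cumsum(q)
    Sa = np.cumsum(qa)
    crit = np.full(256, -np.inf)
    inv = 1.0 / (1.0 - alpha)
    for t in range(256):
        pb, pf = P[t], 1.0 - P[t]
        sb, sf = Sa[t], Sa[255] - Sa[t]
        if pb <= 0 or pf <= 0 or sb <= 0 or sf <= 0:
            continue
        hb = inv * (math.log(sb) - alpha * math.log(pb))
        hf = inv * (math.log(sf) - alpha * math.log(pf))
        crit[t] = hb + hf
    return crit


def _check_nondegenerate(hist: Histogram) -> np.ndarray:
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied bins")
    return hist.q


#: criterion values this close to the maximum count as tied (absorbs float
#: round-off between algebraically equivalent formulations)
_TIE_TOL = 1e-9


def _argmax_lowest(crit: np.ndarray) -> int:
    # ties broken to the smallest T; near-ties within _TIE_TOL count as ties
    best = float(np.max(crit))
    return int(np.argmax(crit >= best - _TIE_TOL))


def max_entropy_threshold(hist: Histogram) -> int:
    """Kapur maximum-entropy threshold.

    Maximizes the summed Shannon entropies of the renormalized background
    (<= T) and foreground (> T) classes over all 256 splits; ties go to the
    smallest T.
    """
    q = _check_nondegenerate(hist)
    return _argmax_lowest(_class_criterion_shannon(q))


def _renyi_candidate(hist_q: np.ndarray, alpha: float) -> int:
    if alpha == 1:
        return _argmax_lowest(_class_criterion_shannon(hist_q))
    return _argmax_lowest(_class_criterion_renyi(hist_q, alpha))


def renyi_threshold(hist: Histogram) -> int:
    """Rényi-entropy threshold with the Sahoo three-alpha weighting.

    Candidate thresholds are computed for alpha = 0.5, 1, 2 (alpha = 1 is
    the Kapur criterion), sorted, and combined with weights built from the
    cumulative probabilities at the extreme candidates and their spacing,
    following the reference auto-threshold plugin.  The combination is a
    convex one, so the result always lies within [min t_i, max t_i].
    """
    q = _check_nondegenerate(hist)
    t1, t2, t3 = sorted(_renyi_candidate(q, a) for a in (0.5, 1, 2))
    P = np.cumsum(q)
    # beta weights depend on how close the three candidates are (<= 5 bins)
    if abs(t1 - t2) <= 5:
        b1, b2, b3 = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        b1, b2, b3 = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    omega = P[t3] - P[t1]
    t_star = (
        t1 * (P[t1] + 0.25 * omega * b1)
        + 0.25 * t2 * omega * b2
        + t3 * ((1.0 - P[t3]) + 0.25 * omega * b3)
    )
    return int(t_star)


def despeckle(intensity: IntensityImage) -> IntensityImage:
    """3x3 median filter with edge-replicated borders."""
    out = ndimage.median_filter(intensity.pixels, size=3, mode="nearest")
    return IntensityImage(pixels=out)


def remove_outliers(mask: BinaryMask, radius: int = 2, min_size: int = 4) -> BinaryMask:
    """Drop foreground components smaller than ``min_size`` pixels.

    ``radius`` is reserved for a median-based variant and currently unused.
    """
    fg = mask.pixels.astype(bool)
    labelled, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    areas = np.bincount(labelled.ravel())
    keep = areas >= min_size
    keep[0] = False
    return BinaryMask(pixels=keep[labelled].astype(np.uint8))


def run_tr_model(image: FluorescenceImage, spec: ThresholdModelSpec) -> BinaryMask:
    """Run one complete thresholding segmenter on an RGB image."""
    if spec.channel == "gray":
        g = to_gray(image)
    elif spec.channel == "red":
        g = red_channel(image)
    else:
        raise ValueError(f"unknown channel {spec.channel!r}")

    if "despeckle" in spec.preprocess:
        g = despeckle(g)

    if spec.threshold_rule == "fixed":
        if spec.fixed_value is None:
            raise ValueError("fixed threshold rule requires fixed_value")
        T = int(spec.fixed_value)
    elif spec.threshold_rule == "max_entropy":
        T = max_entropy_threshold(histogram(g))
    elif spec.threshold_rule == "renyi":
        T = renyi_threshold(histogram(g))
    else:
        raise ValueError(f"unknown threshold rule {spec.threshold_rule!r}")

    mask = binarize(g, T)
    if "remove_outliers" in spec.postprocess:
        mask = remove_outliers(mask, min_size=spec.outlier_min_size)
    return mask
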