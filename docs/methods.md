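# Methods

## Problem setting

A Nile-red-stained filter photographed under a fluorescence microscope
shows bright, red-dominant microplastic (MP) pieces on a dark background.
Quantification proceeds in three steps: segment MP from background
(binarization), count connected pieces, and characterize each piece's
shape and size.  The package implements two segmentation families — global
entropy thresholding and a trainable encoder–decoder — plus the shared
quantification and evaluation machinery, and a synthetic scene generator
that provides exact ground truth for all of it.

## Global thresholding segmenters

All classical recipes factor into a channel reduction `f_{I→G}` and a
threshold rule `f_{G→M}`; binarization is strict (`G_ij > T` is MP).

* **Channel reduction.**  Grayscale uses ITU-R 601 luminance weights
  (0.299, 0.587, 0.114), the convention of the ImageJ-family tools these
  recipes originate from; the weights are overridable.  The red-channel
  variant copies channel 0 unchanged (Nile red fluoresces red-dominant).
* **Kapur maximum entropy.**  For each candidate split T the background
  (≤ T) and foreground (> T) class distributions are renormalized and
  their Shannon entropies summed; T maximizes the sum.  Splits that leave
  a class empty score −∞.  Logs are natural — the argmax is base-
  invariant.  Ties, and near-ties within 1e−9 of the maximum (which
  absorb last-ulp differences between algebraically equivalent
  formulations of the criterion), resolve to the smallest T.
* **Rényi weighting.**  Candidate thresholds `t(α)` are computed for
  α ∈ {0.5, 1, 2} with the two-class Rényi criterion (α = 1 is the Kapur
  criterion), sorted, and combined with the Sahoo rule as implemented in
  the ImageJ auto-threshold plugin: weights β = (1,2,1), (0,1,3) or
  (3,1,0) depending on whether adjacent candidates lie within 5 bins,
  blended through the cumulative probabilities at the extreme candidates.
  The combination is convex, so the result lies in [min t, max t]; the
  final float is truncated to an integer, matching the plugin.
* **Fixed-threshold variant.**  `T = 222` on grayscale with a 3×3 median
  despeckle before thresholding and removal of foreground components
  smaller than `min_size` after.  The despeckle/outlier parameters of the
  original tool are unpublished; the default `min_size = 4 px²` is
  config-exposed and should be treated as a divergence risk when
  comparing against that tool's output.

## Trainable segmenter

A U-Net-style encoder–decoder maps a 3-channel patch to a same-size logit
map: `depth` levels of double 3×3 conv + ReLU with 2×2 max pooling,
channel width doubling per level; the decoder mirrors with nearest-
neighbour upsampling, a channel-halving convolution, skip concatenation,
and a 1×1 output head.  Implemented in numpy with hand-written
backpropagation (im2col convolutions); gradients are validated against
central finite differences in the test suite.  He initialization, seeded.

* **Losses.**  Soft Dice with smoothing s = 1 aggregated over the batch;
  numerically stable BCE-with-logits; or their unweighted sum.  Presets
  mirror the published loss/optimizer grid (`unet1` BCE+SGD, `unet2`
  DiceBCE+Adam, `unet3` Dice+Adam, `unet4`/`mp_net` Dice+SGD).
* **Optimization.**  SGD with momentum 0.9 (default lr 0.1) or Adam
  (default lr 1e−3), batch size 8, with global gradient-norm clipping at
  1.0 by default.  Clipping is load-bearing for Dice + SGD: without it
  the momentum step overshoots into a saturated all-background sigmoid
  whose Dice gradient vanishes, and training collapses.  All defaults
  are config-exposed.
* **Patching.**  Sliding-window tiling with ceil(dim/stride) origins per
  axis and zero padding on the bottom/right (background-colored, so no
  bright content is fabricated at borders); prediction merges overlapping
  probabilities by arithmetic mean and crops the padding.  Extract→merge
  is the exact identity when stride = size.  Training keeps only
  MP-containing patches (over-sampling mode) or seeded-subsamples the
  MP-free ones to a target ratio.
* **Cross-validation.**  Images sorted by ascending MP-pixel count are
  dealt serpentine-fashion (test, CVF1..4, then reversed) so every split
  carries a comparable MP load; 99 images yield a 19-image test set and
  four folds of 20.  Run k trains on three folds, validates on the
  remaining one, and the grand metric is the mean of the four fold means.
* **TTA.**  Photometric-only augmentations (brightness ±25, contrast
  ×0.8/×1.2, hue ±10°) leave geometry fixed, so combining predictions is
  plain pixel-wise averaging of probability maps including the original.
  The exact magnitudes used by the published experiments are not
  available; these defaults are config-exposed.
* **Initialization.**  Random by default.  Transfer learning from
  natural-image benchmarks is out of scope; a weights-file hook
  (`UNet.load`) covers fine-tuning without any network access.

## Quantification

Connected components are 8-connected (the convention of the reference
particle analyzer).  Per piece: area = pixel count; perimeter = Crofton
estimate with 4 directions (asymptotically unbiased on smooth digital
shapes — a radius-50 digital disk measures circularity 0.992);
circularity = `4πA/P²` clamped to 1.0 (digital estimates can exceed 1 on
small or degenerate shapes; a single pixel with zero estimated contour is
defined as maximally compact); Feret diameter = maximum pairwise distance
over the convex hull of the pixel corner points, so a single pixel has
Feret √2 and a 1×10 bar √101.  Shape classes: circularity < 0.3 fiber,
[0.3, 0.6) fragment, ≥ 0.6 particle — the published bands overlap at the
boundaries, so boundary values are assigned to the upper class.  No
minimum object size is applied by default; a filter is config-exposed.

## Evaluation and recovery

Pixel metrics: recall, precision, F1, IoU, balanced accuracy
(mean of recall and specificity).  Zero-denominator ratios are reported
as 0 with an explicit flag so per-image means stay defined.  Multi-
annotator masks fuse by strict pixel-wise majority (ties on even counts
go to background).

Recovery = `100 × predicted / ground truth`, rounded half-away-from-zero
to an integer per sample (the rounding convention is fixed by the
published worked values, e.g. 137.5 → 138); aggregates are the mean and
the n−1 sample standard deviation of the per-sample integers, reported to
one decimal.  The bundled benchmark tables (`mpquant.benchmarks`) carry
the published count pairs for four methods on five spiked and fifteen
clam-derived images; a handful of printed cells in the source tables are
internally inconsistent (one column was printed truncated rather than
rounded, and three aggregate cells do not recompute from their own rows)
and are annotated as such in that module rather than silently matched.

## Synthetic scenes

The generator emulates what matters to segmentation: a dark background
with clipped-Gaussian noise (mean `background_level`, default 20; sd 5;
clipped at ±2 sd — real dark backgrounds have a compact, hard-edged
intensity mode rather than an unbounded tail, and an unclipped tail would
dominate any entropy-based threshold), bright red-dominant objects
(peak 200–255) of three archetypes, and two optional artefacts:

* **halos** — a Gaussian glow (σ = 3 px) around objects, added to the
  image but not the mask, reproducing the false-positive trap of global
  thresholding;
* **dark cores** — interiors of a seeded fraction of objects darkened to
  near-background, reproducing the false-negative trap.

Particles are near-circular ellipses (eccentricity < 0.3), fragments
spiky 10-gons whose alternating radii place them in the fragment
circularity band, fibers thickened random-walk polylines (width 1–3 px,
capped well below arc length).  Rendered archetypes land in their
respective circularity bands for sizes ≥ 8 px, which the property tests
verify through the quantification stage.  A scene spec (including its
seed) fully determines the rendered outputs, bit for bit.

What the generator does *not* emulate: filter-paper texture, optical
blur, vignetting, stitching seams, autofluorescent debris, or calibration
markers.  Tests passing on synthetic scenes therefore demonstrate the
correctness and the qualitative ordering of the methods, not absolute
performance on real micrographs.

## Desk-scale reference study

`mpquant.experiments.segmentation_ordering_experiment` reruns the
qualitative headline comparison at desk scale: 30 scenes (128×128) with
halo strength 0.6 and dark-core fraction 0.5; a depth-2, width-8 network
trained with Dice + SGD for 30 epochs on 200 MP-containing 32×32 patches
(stride 16) from the first 20 scenes; evaluation on the 10 held-out
scenes against the max-entropy pipeline.  These sizes keep the full study
around a minute on one CPU core while preserving the ordering: the
trained model reaches mean IoU ≈ 0.98 where max-entropy thresholding,
caught by the halos and dark cores, stays near 0.50.

## Known limitations

* The numpy network is CPU-bound and desk-scale; the published-scale
  topology (depth 4, width 64, 256×256 patches) is constructible but slow
  to train here.
* The C-VAT despeckle/outlier parameters and the published TTA
  magnitudes, Dice smoothing and learning-rate schedules are not public;
  this package's defaults are documented choices, not reproductions.
* Absolute metric values on real micrographs (e.g. F1/IoU of the
  published test set) require the original image corpus and are not
  reproduced by the synthetic suite.
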