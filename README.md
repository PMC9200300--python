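# mpquant

Quantification of microplastics (MP) in Nile-red fluorescence microscopy
images: segmentation, counting, shape classification and size measurement,
with a recovery-assessment framework for benchmarking methods against
ground-truth counts.

Environmental monitoring labs stain MP extracted from water, sediment or
biota with Nile red, photograph the filter under a fluorescence
microscope, and count the bright pieces.  `mpquant` implements the
computational half of that workflow for two families of segmenters:

1. **Classical global thresholding** — the decision rule

   `M_ij = 1 if G_ij > T else 0`

   applied to a channel-reduced intensity image `G`, with `T` chosen by
   Kapur's maximum-entropy criterion (grayscale; the MP-VAT recipe), by
   Rényi-entropy weighting over α ∈ {0.5, 1, 2} on the red channel (the
   MP-VAT 2.0 recipe, using the Sahoo combination rule of the ImageJ
   auto-threshold plugin), by a fixed `T = 222` with despeckle and
   outlier removal (the C-VAT recipe), or by a user-supplied threshold.
   The Rényi entropy is `H_α(q) = log(Σ_k q_k^α) / (1 − α)` over the
   normalized 256-bin histogram `q`, with the Shannon entropy
   `H_1 = −Σ q_k log q_k` as the α → 1 limit.

2. **A trainable encoder–decoder (U-Net-style) segmenter** — a network
   `M(I; θ)` mapping an RGB patch directly to a per-pixel MP probability,
   trained with soft Dice loss (`1 − (2Σpt + 1)/(Σp + Σt + 1)`),
   BCE-with-logits, or their sum, under SGD-with-momentum or Adam.
   Whole images are tiled into fixed-size patches with a sliding window,
   predictions are merged back by averaging overlaps, and optional
   test-time augmentation (brightness / contrast / HSV shifts) averages
   probability maps over photometrically perturbed copies.  The network,
   its backpropagation and its optimizers are implemented in pure numpy
   and verified against finite differences.

Each binary mask is then quantified per connected component
(8-connectivity): area, Crofton perimeter, circularity `4πA/P²`, Feret
diameter (longest chord, computed on the convex hull of pixel corners),
and the standard shape classes — fiber (circularity < 0.3), fragment
(0.3–0.6), particle (≥ 0.6).  Percentage recovery, `100 × predicted
count / ground-truth count`, aggregates counts into the measure
environmental scientists report.

Because real stained-filter imagery is bulky and rights-encumbered, the
package ships a synthetic scene generator (`mpquant.synthio`) that renders
the three shape archetypes on dark noisy backgrounds with exact
ground-truth masks — including fluorescence halos and dark particle cores,
the two artefacts that make global thresholding over-count (Type 1) and
under-segment (Type 2).  Every downstream stage is testable against this
exact ground truth.

## Worked example

```sh
$ mpquant synth --n-images 4 --out data --seed 3
wrote 4 image/mask pairs to data

$ mpquant threshold --model mp-vat --in data/scene_000.png --out vat_mask.png
wrote mask (848 MP px) to vat_mask.png

$ mpquant quantify --mask vat_mask.png --out summary.csv
7 MP pieces (3 particle / 4 fragment / 0 fiber) -> summary.csv
```

`summary.csv` holds one row per MP piece:

```
id,label,area_px2,area_um2,perimeter_px,circularity,feret_px,feret_um,shape_class
vat_mask,1,45,,33.614,0.500,10.770,,fragment
vat_mask,2,246,,56.042,0.984,19.235,,particle
...
```

Piece 2 is a 246 px² object whose circularity 0.984 classifies it as a
particle with a longest dimension of 19.2 px (µm columns fill in when
`--scale-um-per-px` is given).  Recovery assessment from a CSV of
(ground-truth, predicted) count pairs:

```sh
$ mpquant recover --counts counts.csv --out rec.csv
mean recovery 107.8% (SD 9.2)
```

A mean of 107.8% says the method slightly over-counts: it reports 7.8%
more MP than the annotated ground truth, with a sample-to-sample spread
of 9.2 points.  Training and prediction follow the same pattern
(`mpquant train`, `mpquant predict [--tta]`); see `mpquant COMMAND
--help`.

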