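# Methods

## Problem

Red tides (harmful algal blooms) discolor coastal water and damage
fisheries. Ocean-color imagers such as GOCI (8 bands, 412–865 nm, 500 m
pixels, hourly scenes) observe them synoptically, and the detection task is
binary semantic segmentation of each water pixel: *red tide* versus
*seawater*. Land, the one-pixel coastline rim, and unstudied margins are
carried in the class mask but excluded from training and scoring (the
*valid* mask is `class ∈ {seawater, red tide}`). Scenes are cut into
non-overlapping 32×32 patches for training and stitched back for
whole-scene inference; the train/test split is always by scene (time slot),
never by patch, to avoid spatial leakage between splits.

## Features

Bloom water reflects anomalously in the red and near-infrared, so the model
input augments the radiometry with the normalized difference vegetation
index

    NDVI = (Rrs_865 − Rrs_660) / (Rrs_865 + Rrs_660),

computed from the 865 nm and 660 nm bands, with the convention 0/0 → 0
(such pixels are dark masked water). NDVI is antisymmetric in its inputs
and invariant to common positive rescaling, which is also why brightness
confusers (turbidity) do not move it. The default input stack is the six
shortest-wavelength bands (412, 443, 490, 555, 660, 680 nm) plus NDVI —
7 channels; which six bands constitute the plain-radiometry configuration
is configurable, since red/NIR information beyond 680 nm then enters only
through the index. Channels are min-max normalized to [0, 1] with
statistics fitted on the training split only (z-score and identity are
config options; constant channels are left unscaled with a warning).

## Architecture

The detector is a U-Net: four encoder levels of two convolution stages
followed by 2×2 max pooling, channel width doubling per level (w, 2w, 4w,
8w; bottleneck 16w; default base width w = 64 so the final decoder level
carries 64 channels into a 1×1 two-class head), and a decoder of 2×2
transposed convolutions with skip concatenation and two convolution stages
per level. Softmax gives per-pixel class probabilities; a pixel is called
red tide iff p(red) ≥ 0.5 (ties to red, for determinism). Three changes
define the improved model:

* **ASPC** (atrous spatial pyramid convolution) replaces the plain 3×3
  stages of encoder levels 1–2 (ASPC-3: parallel dilated 3×3 branches at
  rates 1/2/3 carrying 50/25/25 % of the output channels) and level 3
  (ASPC-2: rates 1/2 at 50/50 %). Branch widths are computed by flooring
  the non-primary fractions and assigning the remainder to the 50 % branch,
  so they sum to the block width exactly for any width ≥ the branch count.
  The receptive field of stacked dilated convolutions is
  RF = 1 + Σᵢ dᵢ(k − 1); a pair of 3×3 convolutions at rates (1, 2) reaches
  7×7 and at (2, 3) 11×11, which is the multi-scale context the block adds
  without extra pooling. An impulse-response oracle (all-ones kernels,
  gradient support of the centered output unit) verifies the formula in the
  test suite. ASPC branches are standard dense convolutions; a
  depthwise-separable variant is available by flag.
* **ECA** (efficient channel attention) gates channels after each encoder
  block and the bottleneck (sites are config-driven; an input-stack site is
  available): global average pooling to a 1×1×C descriptor, a weight-shared
  1-D convolution across channels, a sigmoid, and per-channel rescaling.
  The 1-D kernel size follows the adaptive rule
  t = int(|log₂C + b| / γ), k = t if odd else t + 1 (γ = 2, b = 1,
  minimum 1), overridable with any odd size.
* **Dropout** (rate 0.3) sits at the bottleneck→decoder transition, before
  up-sampling.

An ASPP block (1×1 conv, three depthwise-separable dilated 3×3 convs at
rates 1/3/5, and a global-pool branch, fused by 1×1 convolution) is
provided as the pyramid the ASPC design descends from.

Every convolution stage is conv → batch normalization → ReLU. Batch
normalization is adopted as standard practice and can be disabled per
config; it is the package's choice, not part of the published recipe.

### Baselines

* **Basic U-Net** — the same trunk with all-conv stages and no attention;
  **U-Net + ECA** — attention without ASPC (the middle ablation rung).
* **FCN-8s** — a slim VGG-style stack sized for 32×32×7 inputs (widths w,
  2w, 4w, 8w, 8w; one conv stage per pooling step) with 1×1 score layers on
  the pool3/pool4/final streams fused through learned 2× up-sampling steps.
  The published description fixes only that its training hyperparameters
  match the improved U-Net, so the backbone is deliberately lightweight
  rather than an ImageNet VGG16. Disabling the pool3 skip gives FCN-16s
  behavior.
* **Pixel SVM** — an RBF support-vector classifier (C = 1, gamma = "scale")
  on single-pixel feature vectors, trained on a seeded subsample of at most
  50 000 valid pixels. It sees no spatial context by construction.

## Training

Masked pixelwise cross-entropy: mean over valid pixels only, so land,
coastline and unstudied pixels contribute neither loss nor gradient. The
published protocol fixes Adam, batch size 50, dropout 0.3 and 120 epochs;
it names no loss or learning rate, so the package defaults to
cross-entropy and Adam's canonical 1e-3. Patches are shuffled each epoch
with the config seed; the held-out scene's patches serve as validation and
the parameters of the best-validation-F1 epoch are retained. Early
stopping is off by default. No data augmentation is applied.

## Evaluation

With red tide positive, over pooled valid pixels of the test split
(micro-averaged, matching single-number-per-table reporting):
accuracy, precision and recall in percent and F1 = 2PR/(P + R) on the 0–1
scale, displayed to two decimals. Precision, recall and F1 are defined as 0
when their denominators vanish. The F1 of any report always lies between
its precision and recall (harmonic-mean bound, property-tested).

## Neural-network engine

No deep-learning framework is part of the package's dependency set; the
models run on a small NumPy reverse-mode autodiff engine
(`redtidenet.nn`): im2col + BLAS matmul dilated convolution, kernel-2
stride-2 transposed convolution (a per-pixel linear map, since windows do
not overlap), 2×2 max pooling with first-max tie-breaking, batch
normalization with running statistics, channel-wise 1-D convolution for
ECA, inverted dropout, and a fused masked softmax cross-entropy. Everything
is float32; parameters use He initialization from a per-model seeded
generator, so identical config + seed reproduces identical parameter
vectors and training trajectories. Every differentiable op is verified
against central finite differences in the test suite.

## Synthetic scenes

The generator provides the study conditions for the end-to-end tests. A
scene is built from (a) a land strip with a wavy coast, its one-pixel
coastline rim, and an unstudied margin; (b) a bloom mask from a
Gaussian-filtered white-noise field thresholded at the quantile matching
the target bloom fraction — `banded_dispersed` uses a short anisotropic
correlation length (many elongated streaks), `concentrated` a long
isotropic one (few compact patches); (c) per-class spectra: a fixed
clear-seawater baseline (order 0.005–0.025 by band), bloom pixels with the
660/865 pair solved so the class-mean NDVI contrast equals the
`ndvi_contrast` parameter exactly in the noiseless limit, elevated 680/745
response, and a relative blue-green (443–555 nm) shift (default −15 %);
(d) turbid confusers: seawater scaled ×1.8 across all bands; and (e)
additive per-band Gaussian noise (sd 0.005 by default), clipped at zero.
Turbid pixels carry proportionally (×1.8) scaled noise so that their NDVI
distribution is exactly that of clear seawater — positive scaling commutes
with both the index and the zero-clipping — making them bright but
spectrally indistinguishable, which is the confusion that defeats
brightness thresholds. Defaults: 5 scenes (4 train, 1 test) of 256×256,
bloom fraction 0.15, turbidity 0.10, land 0.08, contrast 0.25.

What the generator does **not** emulate: atmospheric-correction residuals,
clouds, sensor striping, spatially varying water types, label noise at
bloom boundaries, or any radiative-transfer realism. Passing the
end-to-end tests therefore shows that the pipeline learns and ranks
spectral-plus-spatial signal as designed — not that real-scene accuracies
are reproduced.

## Benchmark problem sizes

The seeded benchmark (`redtidenet.benchmark`) trains at base width 8 with
30 epochs and scores on the held-out scene; the SVM baseline subsamples
4000 training pixels. These are the package's desk-scale settings — the
architecture is identical to the full-width model up to channel counts, and
the synthetic task saturates well within 30 epochs. The full-width,
120-epoch configuration remains the library default for real use.

## Known limitations

* The synthetic task is spectrally much cleaner than real imagery; all
  U-Net variants converge to high F1 (≈0.94–0.98) on it, and the seeded
  benchmark consistently scores the plain U-Net at or slightly above the
  improved model. That is a property of the conditions, not a defect of
  the blocks: with a strong per-pixel spectral signal and sharp synthetic
  boundaries, full-resolution rate-1 capacity is worth more than the
  multi-scale context ASPC buys, whereas the regime the improved recipe
  targets — weak separability between bloom edges, turbid water and
  seawater — is precisely what a simple generator does not reproduce. The
  benchmark therefore validates the pipeline and the baselines' relative
  difficulty (pixel SVM and the 32×32-patch FCN-8s rank clearly below all
  U-Nets), not the published architecture ranking.
* The NumPy engine is single-threaded BLAS-bound and roughly an order of
  magnitude slower than a compiled framework; full-width 120-epoch training
  is desk-feasible but slow.
* FCN-8s on 32×32 patches pools to a 1×1 bottleneck and up-samples through
  learned 2× steps, which is coarse at this patch size; its weak scores on
  the benchmark reflect that architectural mismatch, as expected for the
  comparison.
* "GeoTIFF" scenes are plain multiband TIFFs with a JSON sidecar for band
  centers and georeferencing pass-through; no CRS handling is attempted.
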