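# Methods

## Problem and approach

Tomatoes ripen from the inside out, so no single sensing modality determines
maturity reliably: color imaging sees only the exocarp, Vis/NIR transmission
spectroscopy sees pigment and water/carbohydrate signatures but confuses
near-ripe interiors, and grip-pressure (haptic) sensing measures firmness but
nothing about color. `ripefuse` implements feature-level fusion of the three
modalities: each modality is preprocessed, encoded by its own deep network
into a fixed-length embedding, the embeddings are concatenated, and a fully
connected residual network classifies the splice.

The pipeline is organized as

1. **preprocessing** — image: grayscale threshold-50 background removal and
   resize to 150×150; spectrum: black-and-white correction
   `R = (R_raw − R_d) / (R_w − R_d)`; haptic: zero-phase order-4 Butterworth
   low-pass at 10 Hz (100 Hz sampling, 15 s traces);
2. **feature extraction** — image: VGG16-style stack (conv blocks of
   2, 2, 3, 3, 3 layers, each ending in a /2 max-pool; a 150×150 input leaves
   a 4×4×512 tensor, flattened to the 8192-long tap); spectrum: three
   conv+BN+ReLU+maxpool blocks with 10 channels in the last block, globally
   max-pooled to a 10-long tap; haptic: a single-layer LSTM with hidden size
   64, tapped at the final hidden state;
3. **fusion** — the splice `[m | n | z]` of length 8192 + 10 + 64 = 8266 with
   no scaling or reweighting;
4. **classification** — a fully connected network 8266 → 512 → 512 → 256 → 3,
   every hidden layer followed by batch normalization, ReLU and dropout, with
   an identity-skip residual block of two 512-wide FC layers (each followed by
   batch norm and dropout) between the second and third layers, ReLU after
   the skip addition.

Extractors are trained first as standalone unimodal classifiers
(cross-entropy, Adam 1e-3, dropout 0.5 where present), then frozen; the
fused network trains on cached taps with best-validation-epoch
checkpointing.  Splits are stratified at the fruit level (64/16/20
train/validation/test) so the four rotations of a fruit can never leak
across splits.

## The phantom generator

No public dataset of tri-modal tomato acquisitions exists, so the package
ships a synthetic phantom generator whose class-conditional statistics are
calibrated to reported measurements on real greenhouse tomatoes.  It is the
test bed for every downstream stage.

| quantity | immature | semi-mature | mature | source of the value |
|---|---|---|---|---|
| exocarp red fraction | < 0.10 | 0.10–0.90 | > 0.90 | stage definitions |
| SSC mean (Brix) | 4.15 | 4.85 | 5.5 | reported class means |
| firmness mean (MPa) | 2.82 | 1.96 | 1.1 | reported class means |
| grip plateau (kPa) | 52–65 | 26–46 | 13–26 | reported class ranges |

Heterogeneous-ripening categories (negative1: light-green cavity; negative2:
white cavity; positive: uniformly ripe) all render ≥ 95 % red exteriors and
plateau near 29 / 29 / 13 kPa — the designed blind spots: images cannot
separate any of the three, spectra separate negative1 but not negative2 from
positive, haptics separate both negatives from positive but not from each
other.

Design choices where the calibration source gives no value (chosen once, as
package defaults):

* **Distribution shapes.** SSC and firmness are truncated Gaussians
  (sd 0.35 Brix / 0.30 MPa — class histograms overlap mildly); plateau
  levels are uniform inside the calibrated closed ranges, making the three
  stage ranges disjoint by construction; heterogeneous plateaus are Gaussian
  (sd 1 kPa) around the category means.
* **Spectra.** The corrected-transmittance template is
  `baseline + 0.30·Σ Gaussians(630, 730, 830, 1070 nm; σ 8.5 nm ≈ 20 nm FWHM)
  + g·B(λ)`, where `B` is a smooth window over 600–950 nm and the band gain
  `g` is 0.10 / 0.25 / 0.40 for immature / semi / mature — giving the
  reported mature > semi > immature ordering of band intensity.  The window
  edges are steep (logistic width 5 nm) so the designed 630 nm feature, not
  the window slope, sets the local maximum on the 1 nm grid.  Acquisition
  noise is white (sd 0.01) plus a 3 % relative band-gain jitter; negative1 /
  negative2 sit 5× / 1× the noise sd below the positive template, encoding
  "clearly separated" versus "slightly different".  The generator emits the
  full raw/white/dark triplet constructed so that the correction recovers
  template + noise exactly; the default grid is 751 points (350–1100 nm at
  1 nm), configurable.
* **Haptic traces.** 1500 samples: near-zero approach (0–3 s), half-cosine
  grip ramp (3–5 s), plateau (5–15 s).  Vibration is injected as sinusoids at
  15 / 23 / 37 Hz (0.6 kPa each) plus white noise (0.1 kPa), concentrating
  disturbance energy above the 10 Hz cutoff so the filter stage is genuinely
  exercised (the tests require ≥ 20 dB suppression above 10 Hz).
* **Images.** A disc (radius ≈ 0.42 of the frame) on a gray-15 background;
  the red region is the top-q fraction of a smooth angular random field, so
  the red fraction is exact by construction and blotches look organic.
  Rotation index shifts only the field phase — nuisance geometry, never
  class statistics.
* **Determinism.** Every draw is keyed by (dataset seed, fruit id, rotation,
  modality) through `numpy.random.SeedSequence`, so a manifest reproduces
  its dataset byte for byte.

What the phantoms do *not* emulate: real optics (illumination, specular
highlights, shading), contact mechanics, instrument line shapes, or
biological covariance between modalities beyond the shared class label.
Passing tests therefore demonstrate that the pipeline's mechanics — layout
contracts, preprocessing algebra, training behavior, and the
modality-blind-spot logic — are correct, not that the classifier would reach
any particular accuracy on real fruit.

## Numerical and training choices

* The neural layers are implemented in numpy with explicit backprop
  (im2col convolutions, BPTT for the LSTM) and are verified against central
  finite differences in the test suite.  Evaluation mode is deterministic:
  fixed weights + fixed input give bit-stable features.
* Grayscale conversion uses Rec.601 luma (0.299/0.587/0.114); foreground is
  *strictly* greater than the threshold.  Segmentation recomputes its mask on
  the resized pixels, which makes the operation exactly idempotent.  An empty
  foreground is a warning, not an error.
* Correction channels with `R_w = R_d` are set to NaN with a warning (never
  silent infinities); extractor input preparation interpolates NaN channels.
* The Butterworth filter is applied forward-backward (`sosfiltfilt`): unit DC
  gain, no phase distortion of the plateau onset, and the single-pass −3 dB
  point at the cutoff becomes −6 dB.  The plateau summary of a trace is the
  mean over the longest contiguous run of samples in the top quartile of
  filtered levels — robust to approach/ramp length.  A fruit's overall
  pressure is the mean of its four equatorial plateau summaries.
* Batch-norm running statistics are recalibrated over the training set after
  every epoch (momentum-1 pass with dropout off), and best-validation
  checkpoints store the *full* state including those statistics.  With
  ~10²-sample training sets and batch 16–32, plain running averages drift far
  enough from the deterministic eval network to destroy restored checkpoints.
* Softmax ties break toward the lowest class index (numpy argmax).
  Zero-denominator precision/recall return 0 with a warning.  One-vs-rest
  macro averaging (unweighted) is reported alongside per-class values.
* Unstated architecture details, fixed once: 1D-CNN kernels 7/5/3 with
  channels 16/32/10 and stride-2 pools (minimal choices reaching the 10-long
  tap); LSTM depth 1 with forget-gate bias +1; image head 8192 → 256 → 64 → 3;
  Adam 1e-3, batch 32, 50 epochs at reference scale; dropout 0.5 in the
  image head and fusion net.  No pretrained weights anywhere — everything
  trains from scratch, so the artifact needs no downloads; checkpoints can
  be supplied through `ripefuse.modelio`.

## Presets and problem sizes

The `reference` preset keeps every reference dimension (150×150 inputs, full-width
extractors, 8266-long splice, 79/60/75 fruits) and is used for the
single-forward-pass dimension contracts.  The `desk` preset is the package's
CPU-scale configuration for the seeded end-to-end experiments: 75×75
segmented images, a 1/8-width image extractor (tap 4×4×64 = 256, splice
256 + 10 + 64 = 330), LSTM input stride 10, 20 fruits per stage × 4
rotations, and 8–40 epochs per model.  Reduced-width configurations are
flagged `reference_exact = False`; the splice layout `[m | n | z]` and all
preprocessing are identical in both presets.  The heterogeneous experiment
uses 24 training + 6 validation fruits per category (one rotation each),
giving the 18-sample validation confusion matrix, with extractors frozen
from the stage experiment and the fused classifier retrained on category
labels.

## Known limitations

* The desk-scale fused accuracy comparison is run on phantoms that are
  separable by construction; it verifies the *direction* of the
  unimodal-versus-fusion comparison, not effect sizes on real produce.
* The image extractor's 8192-long tap is realized as the flattened final
  pooled convolutional output (4×4×512 for a 150×150 input); a custom
  8192-unit fully connected tap would satisfy the same contract and is not
  distinguishable from the available description.
* Recurrent backprop over full 1500-step traces is supported but slow in
  pure numpy; the desk preset subsamples by 10 (flagged non-reference).
* The fused network applies no modality rebalancing by design (plain
  concatenation); with very small training sets this makes optimization
  sensitive to initialization, mitigated by the batch-norm recalibration
  described above.
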