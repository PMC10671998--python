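# Methods

## Scope and data model

The package detects a single class of anomaly ("lesion") in 2-D grayscale
scans. Boxes live in normalized continuous coordinates on the unit square,
corner format (x_min, y_min, x_max, y_max), origin top-left. Every image
carries a fixed-length array of K = 3 box slots; unused slots hold the
all-zero sentinel. Sentinel-ness is decided everywhere by one rule: a box
whose area is below 1e-4 of the unit square is empty. The area form (rather
than a literal all-zeros test) matters during training, where regressed
sigmoid coordinates can collapse a slot to numerically nothing without ever
reaching exact zeros; such slots drop out of the IOU loss and of prediction
output the same way written sentinels do.

Ground-truth arrays are canonically sorted by (y_min, x_min) with real boxes
first, so the slot-aligned training loss sees a deterministic target order.

## Synthetic scan generator

The generator emulates the structure of spectral-domain OCT B-scans of
layered tissue at desk scale:

* a stack of `n_layers` horizontal bands (default 4) with reflectivities
  drawn uniformly from `layer_intensity_range` (default 0.25–0.75) and
  smoothly undulating sinusoidal interfaces, softened by a sigma 1.5 px
  Gaussian;
* fully developed multiplicative speckle: the clean image is multiplied by
  gamma noise with shape k = `speckle_shape` (default 3) and unit mean, so
  speckle contrast is 1/sqrt(k); smaller k means harsher speckle;
* zero to three elliptical lesions (count uniform on `lesion_count_range`,
  default 1–3, matching the one-to-three-lesions-per-image regime the
  detector targets), each an additive intensity perturbation of
  `lesion_contrast` (default +0.35, hyper-reflective) with Gaussian-softened
  edges, placed fully inside the frame; the returned box is the tight
  axis-aligned box of the solid (mask >= 0.5) part of the perturbation;
* final clipping to [0, 1].

The default frame is 128x128 px (desk scale); the nominal full scan size of
500x412 px is available through the parameters. A scan is a pure function of
(params, index): the stream is seeded with the pair, so datasets are
bit-reproducible.

What the generator does **not** model: physical A-scan formation,
depth-dependent attenuation and shadowing under lesions, refraction at
interfaces, vendor post-processing, or 3-D context. Passing tests on this
phantom therefore demonstrates that the pipeline's mechanics (geometry,
losses, training loop, evaluation protocol) are correct and that the
detector can in principle recover simulated lesions — not that it reaches
clinical performance on real scans.

## Augmentation

Geometric only, applied identically to image and boxes: optional left-right
flip (probability 0.5 when enabled), rotation uniform in +/- 0.02 of a full
turn (+/- 7.2 deg), isotropic zoom uniform in 1 +/- 0.2, all about the image
centre. The rotation unit ("factor of a full turn") follows the conventional
semantics of random-rotation augmentation layers. Boxes are mapped as the
axis-aligned hull of their transformed corners and clipped to the frame; a
box that loses more than 90% of its area is dropped to sentinel. "Flipped
about the horizontal axes" is implemented as a left-right flip and is
toggleable. Augmentation draws come from an explicit generator argument so
epochs are reproducible.

Patch extraction pads by edge replication to the next multiple of the patch
size (so 250 px becomes 256 = 8 x 32) and tiles row-major without overlap;
cropping would discard border lesions.

## Model

**Patch encoder.** Patches and half-stride sliding-box query windows are
flattened and linearly embedded to 64 dimensions. The gate computes
softmax-normalized scaled dot products of embedded queries against embedded
patches and adds the score-weighted values to the patch embeddings. Three
departures from the most literal reading of the architecture sketch were
forced by verified failures, and are design choices of this package:

1. *Gating adds, not replaces.* At initialization the score matrix is
   near-uniform, so replacing tokens by score-weighted values averages all
   patches together before any positional encoding exists — the network
   output became constant across images. Adding the attended values to each
   patch's own embedding keeps spatial identity while still letting
   attention emphasize foreground, which is the attention-gate semantics in
   the segmentation literature.
2. *Residual around the convolution stage.* Two 3x3 stride-3 convolutions
   reduce a 4x4 (or even 8x8) token grid to 1x1; after nearest-neighbour
   upsampling every token is identical and lesion position is
   unrecoverable. The conv output is therefore added back to the gated
   tokens as a residual.
3. *LayerNorm on the encoder output.* Without it, token magnitudes grew
   unboundedly during training (observed ~3e3), saturating downstream
   softmax and sigmoid units and freezing optimization.

The 1/sqrt(d) logit scaling (not written in the attention equations this
implements) is included for numerical stability.

**Trunk and head.** A learnable summary token is prepended, a learned
positional table (N+1, D) added, then `n_blocks` (default 8) pre-norm
transformer blocks: LayerNorm -> 4-head self-attention -> residual;
LayerNorm -> MLP (widths 128, 64, GELU, dropout 0.1) -> residual. After a
final LayerNorm, an MLP head on the summary token emits 4K sigmoid outputs;
per-box coordinate sorting (min/max of each pair) guarantees valid boxes for
any head output. There are no objectness scores, anchors or NMS: the model
always emits K slots and empties unwanted ones.

## Loss

L_total = (L_MSE + L_difference + L_IOU) / 3, each component in [0, 1], so
the combined loss is normalized to [0, 1] ("combined and normalized" is
resolved as the mean).

* **L_MSE** — mean squared error over all 4K normalized coordinates of the
  slot-aligned arrays.
* **L_difference** — 1 − SSIM between soft rasterized union-of-boxes masks
  of the two arrays. Masks use anti-aliased (pixel-coverage) box edges,
  union by complement product, and a sigma 2 px Gaussian smoothing; SSIM
  uses a uniform 7x7 window, K1 = 0.01, K2 = 0.03, sample covariance, valid
  windows only — numerically identical to the standard reference
  implementation on the interior. The mask (rather than image-crop) reading
  of "structural similarity between predicted and actual pairs" was chosen
  so the term is computable from boxes alone and smooth in the coordinates.
* **L_IOU** — 1 − mean IOU over slot pairs where at least one side is a
  real box; sentinel pairs are excluded by the zero-area test; all-sentinel
  arrays give 0. Plain IOU is kept (no generalized-IOU surrogate): when
  boxes are disjoint the IOU gradient is zero and L_MSE provides the
  translation signal.

The whole loss is differentiated by the package's own reverse-mode autodiff
core (`octdet.nn`), a tape-based engine over numpy float64 arrays providing
exactly the primitives the model needs; all primitives are checked against
central finite differences in the test suite.

## Training

Defaults: Adam (AdamW selectable), learning rate 5e-4 — the leading value
of the ablation this design follows, even though it is absent from the
coarser candidate list quoted alongside it — batch size 4, 200 epochs,
2 augmentation draws per image per epoch, dropout 0.1, global-norm gradient
clipping at 5, one seeded generator for init/shuffling/augmentation/dropout.
Data are split 60%/10%/30% into train/validation/test by seeded shuffle with
floor allocation (remainder to the largest split, train). The best-validation
checkpoint is saved each epoch; there is no early stopping. A checkpoint is
a single archive of the JSON config plus parameter arrays and restores
bit-identical inference.

## Evaluation protocol

Predictions and ground truth are matched greedily in descending IOU order,
one-to-one; unmatched ground-truth boxes enter as IOU-0 pairs. A matched IOU
strictly above 0.5 is a true positive, everything else a false positive
(IOU exactly 0.5 counts as FP, since the protocol defines TP by strict
inequality); TN = FN ≡ 0 because there is a single class and no negative
images. Consequently sensitivity ≡ 1 whenever anything was detected,
accuracy ≡ precision, and F1 = 2p/(p+1). Dataset-level scalar metrics are
averaged over images; TP/FP are summed counts. An evaluation with no
detections at all reports zeros and a `no_detections` flag.

## Scaled-down benchmark and known limitations

The acceptance benchmark (`scripts/acceptance.py` and the end-to-end test)
uses 300 single-lesion 128x128 scans, a 2-block model and 30 epochs so a
full run fits in minutes on one CPU; these problem sizes are the package's
chosen desk-scale operating point.

Two limitations of detector *training* at this scale are documented rather
than hidden:

1. **Collapse attractor of the composite loss.** When the model cannot yet
   localize, the SSIM term prefers an empty predicted mask over a misplaced
   box and the IOU term gives zero gradient for disjoint boxes; box slots
   then shrink below the sentinel area and training settles at a constant
   loss predicting nothing. On the 300-scan benchmark this state persists
   through at least 200 epochs.
2. **Sample complexity of direct box regression.** With the composite loss
   replaced by pure coordinate MSE the model instead memorizes the training
   images (train MSE below 1e-3) while held-out IOU stays near 0.05;
   generic learners fitted to patch-level features fare no better at this
   sample size. The underlying task is solvable — a fixed
   background-subtraction blob detector reaches held-out mean IOU 0.50 on
   the same data — but learned from-scratch box regression needs
   substantially more data and optimization than the desk-scale budget
   provides. The acceptance script reports the honestly measured recovery
   factor either way.

Degenerate inputs: empty box tables load as all-sentinel arrays; images are
clamped to [0, 1] on load; resizing is bilinear and exact for identity and
constant inputs; IOU of two empty boxes is defined as 0; SSIM of two empty
masks is 1 (loss 0); evaluation of an empty split raises.
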