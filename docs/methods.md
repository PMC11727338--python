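# Methods

## Problem and model

The package segments tumor-like foreground in 2-D grayscale or RGB medical
images: given an image x and a per-pixel binary ground-truth mask m, a model
f_θ is trained so that f_θ(x) ≈ m. The model is an encoder–decoder
convolutional network (U-Net family) whose contracting path contains two
spatial attention gates.

**Feature blocks (FP).** Each block applies three same-padded 3×3
convolutions with a ReLU between the first/second and second/third
convolutions; the last convolution is not followed by an activation. The
channel count changes at the first convolution and is constant thereafter.
The blocks are plain feed-forward; an optional residual-add flag (off by
default, with a 1×1 projection when widths differ) is provided for
ablations.

**Spatial attention gates (FSA).** At input width C, the gate path window-
pools the features by a factor of 2 with both average and max pooling,
concatenates the two pooled maps channelwise (2C channels), mixes them with
a 1×1 convolution (2C → 2C), and squashes with a logistic sigmoid so every
gate value lies strictly in (0, 1). The value path is a 1×1 convolution
(C → 2C) of the max-pooled features. The block output is the elementwise
product: resolution halves, width doubles. A `force_open` hook bypasses the
gate (gate ≡ 1), reducing the block to a pooled projection — this is the
ablation used to verify that attention is live.

**Layer plan.** With base width 16 (first block's output width c1 = 16):
encoder widths [16, 32, 32, 64, 128, 128, 256] at block boundaries
(FP1, FSA1, FP2, FP3, FSA2, FP4, FP5-bottleneck), stride-4 max pooling after
FP2 and FP4, attention pooling 2 inside FSA1/FSA2, so the bottleneck sits at
1/64 of the input resolution (8×8 for a 512×512 input). The decoder
upsamples by [4, 2, 4, 2] (nearest-neighbour, then a triple-conv block),
concatenating the encoder skip of matching resolution — [FSA2, FP3, FSA1,
FP1] in decoder order — and narrowing to [128, 64, 32, 16]. A final 3×3
convolution to `out_channels` (default 1) and a sigmoid produce per-pixel
foreground probabilities. The default 3-channel full-width network has
3,049,761 parameters; the test suite checks this against a closed-form sum
over the plan. `width_multiplier` rescales c1 (all other widths are fixed
multiples of c1), preserving the topology exactly at any scale.

Upsampling is nearest-neighbour interpolation followed by convolution, not
transposed convolution, avoiding checkerboard artifacts and keeping the
backward pass trivial. All convolutions are same-padded stride-1; inputs
must have spatial dimensions divisible by 64 (the product of the pooling
factors), which is validated with an explicit message.

**Why this decoder order.** The stage-wise upsample factors must retrace
the encoder's pooling factors in reverse ([2,4,2,4] down ⇒ [4,2,4,2] up) so
that every decoder stage lands exactly on a stored skip resolution; any
other order breaks the bookkeeping. Likewise the gate convolution's input
width is necessarily 2C, the width of the concatenated pooled pair.

## Numerical engine

The network runs on an in-package reverse-mode automatic-differentiation
engine over float64 NCHW NumPy arrays (`attnseg.nn.autodiff`): im2col
(`sliding_window_view` + `tensordot`) convolution whose input gradient is a
convolution with the transposed, spatially flipped kernel; argmax-routed
max-pool backward; uniform-spread average-pool backward; sum-pooled
nearest-upsample backward. Every operator's gradient is tested against
central finite differences, and the convolution forward against a
nested-loop oracle. Weights are He-uniform initialised from a seeded
generator; biases start at zero. A `no_grad` context disables graph
construction for inference.

## Training

The loss is mean per-pixel binary cross-entropy with predictions clipped to
[ε, 1−ε], ε = 1e-7. The optimiser is Adam (default lr 1e-4, batch 8);
optimiser, learning rate and batch size are exposed in `TrainCfg`. Data are
split **by patient ID**: round(0.8 · n_patients) patients train, the rest
test, both sides forced nonempty; the split is seeded and all slices of a
patient land on one side. Held-out mean DSC is computed each epoch and the
best-DSC checkpoint is retained. Validation metrics are computed on the
held-out fold itself rather than a third split — a deliberately simple
protocol that is methodologically weak for model selection; a three-way
split can be had by passing a distinct `val_patients` set. The data layer
logs every patient whose images the training loop reads, so leakage is
testable rather than assumed. Non-finite losses abort with a diagnostic.

## Phantom generator

The generator emulates the regimes that make tumor segmentation hard,
without anatomical simulation:

* **Background**: a Gaussian-filtered noise field (texture scale ~size/8)
  around a per-patient base level in [0.22, 0.38], std 0.03 — a smooth,
  patient-specific intensity drift.
* **Lesions**: ellipses (axis ratio 0.92–1.08) whose boundary radius is
  modulated by a 3-harmonic Fourier perturbation of amplitude ≤ 0.12,
  giving irregular but area-bounded blobs (effective radius within
  [0.81 r, 1.21 r]).
* **Contrast**: a constant additive offset inside the lesion, so at
  noise_sd = 0 the mean foreground shift equals `contrast` exactly — this
  makes the alignment invariant testable to machine precision.
* **Noise**: additive Gaussian (default), Rician optional.
* **Scenarios**: `low_contrast` (contrast 0.12 vs default 0.4),
  `small_tumor` (radius 2–4 px), `overlapping` (second lesion placed at
  0.4–0.75 of the summed radii, guaranteeing touching or merged blobs).

Defaults (64 px, one lesion of radius 6–14, contrast 0.4, noise 0.03) are
chosen so a desk-scale network separates foreground reliably: the phantom is
a controlled benchmark, not a hard perception problem. Everything derives
from `SeedSequence` children of the spec seed — same spec, same bits.
Per-patient style (background level, texture scale) is shared across a
patient's slices so patient identity carries real signal and split leakage
is detectable statistically.

What phantoms do **not** emulate: anatomy, multi-modal channels
(T1/T2/FLAIR), scanner bias fields, partial-volume boundaries, 3-D
structure. Passing tests therefore demonstrate correctness of the
machinery and learnability under controlled conditions, not clinical-grade
performance on real MRI.

## Preprocessing

Stage order is fixed: normalize → resize → equalize → denoise, with
augmentation last and only in training mode. Masks are resized with
nearest-neighbour interpolation and images bilinearly, so masks stay
strictly binary (asserted after every stage). Min-max normalization is
re-applied after equalization/denoising so outputs span exactly [0, 1].
Augmentation draws flips (horizontal/vertical, p = 0.5 each), a rotation in
±15°, and an integer translation within ±5% of the image size from a
seeded stream; the identical parameters are applied to image and mask, and
out-of-frame pixels are zero-filled. Translations are integer-pixel so the
single-pixel displacement test is exact. Gaussian denoising (σ = 0.5 px) is
the default; median and off are available.

## Metrics

* **DSC** 2|A∩B|/(|A|+|B|); both-empty = 1.0, one-empty = 0.0. On binary
  masks DSC equals F1 = 2PR/(P+R), which the suite asserts to 1e-12.
* **Precision / recall / accuracy** from pixel confusion counts;
  zero-denominator cases return 0.0 (documented sentinel).
* **ROC-AUC** via an explicit sweep over all distinct score thresholds and
  the trapezoidal sum Σ(FPRᵢ−FPRᵢ₋₁)(TPRᵢ+TPRᵢ₋₁)/2; single-class truth
  raises. The sweep construction makes the value invariant under strictly
  monotone score transforms and equal to the Mann–Whitney pairwise rank
  statistic.
* **HD95**: boundaries are 4-connectivity erosion differences; directed
  distances are Euclidean via distance transform; the per-direction 95th
  percentile uses linear interpolation; the result is the max of the two
  directions. Empty masks raise, and such images are excluded from HD95
  averaging with an excluded-count in the report.
* **Aggregation** over ≥2 independent runs: per-metric mean, sample SD
  (ddof = 1), and a Student-t 95% CI half-width (t₀.₀₂₅,ₙ₋₁·SD/√n);
  percentile bootstrap optional.

Metrics are computed per image and then averaged over the test set (rather
than pooling pixels globally), matching how DSC is conventionally reported.

## Postprocessing

Probability maps are thresholded at 0.5 (≥ counts as foreground), labeled
with 8-connectivity by default, and components smaller than a minimum size
are removed. The minimum is specified at a 512×512 reference resolution
(default 10 px) and scaled by area for other sizes; a largest-component
mode is available by flag. Small-component filtering is idempotent and can
only remove foreground.

## Desk-scale study conditions

The regression/acceptance configuration trains a quarter-width
(width_multiplier 0.25, 191,121 parameters) single-channel network on 200
phantoms — 25 patients × 8 slices at 64×64, default scenario — with Adam at
lr 1e-3, batch 8, for 15 epochs, evaluating on the 5 held-out patients.
Problem sizes were chosen so the full cycle runs in about a minute on one
CPU while leaving a wide margin over the DSC ≥ 0.90 recovery bar (a pilot
with these settings crossed 0.90 by epoch 7 and reached ~0.98 by epoch 10).
The library default lr stays at 1e-4; 1e-3 is the documented desk-scale
setting.

## Known limitations

* 2-D only; NIfTI volumes are consumed slice-wise along the last axis.
* The engine is CPU NumPy: full-width 512×512 training is out of reach;
  that regime is what the `width_multiplier`/phantom machinery exists to
  scale down.
* Binary foreground only; `out_channels > 1` exists as a head option but no
  multi-class loss is provided.
* The phantom's simplicity means metric ceilings (DSC ≈ 0.98) say nothing
  about real-MRI difficulty.
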