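# Methods

This note documents the models, conventions and numerical choices behind
`incunet`, and what its phantom-based tests do and do not establish.

## Problem setting

Whole-tumor segmentation in multi-modal brain MRI shaped like BraTS 2019:
each patient contributes four co-registered 240×240×155 volumes (T1, T2,
T1ce, FLAIR) and an integer label volume over {0, 1, 2, 4} (background,
necrotic/non-enhancing core, peritumoral edema, enhancing tumor). The
package targets the binary whole-tumor task by default — labels {1, 2, 4}
are collapsed to 1 — because the evaluation it mirrors reports a single
dice/sensitivity/specificity triple per model; the nested sub-region labels
are preserved end to end so multi-class targets remain possible.

Data are assumed skull-stripped and co-registered upstream; the package does
not perform either.

## Two-stage pipeline

Roughly 43% of training slices contain tumor tissue, so segmenting every
slice wastes most of the compute on easy negatives and skews the loss. The
pipeline therefore (1) classifies each axial slice as tumor/no-tumor using
only the FLAIR and T2 channels — the water-sensitive sequences on which
edema is bright — and (2) runs the pixelwise segmentation network, which
sees all four modalities, only on flagged slices (`two_stage_predict`,
gate threshold 0.5, configurable, and a `--no-gate` path that segments every
slice). Segmentation training uses only tumor-bearing slices; tumor-free
slices are the classifier's responsibility. Both gated and ungated
evaluation paths exist because either convention is defensible at test time.

## Preprocessing conventions

* **Crop.** A fixed centered 176×176 window (offsets (32, 32) on a 240×240
  grid), validated per volume against the brain bounding box — the min/max
  nonzero rows and columns over all slices and modalities. Validation
  refuses, never shifts: a brain voxel outside the window is an error, so
  the documented "no information loss" property of the 46.2% voxel
  reduction (1 − 176²/240² = 0.46222) is enforced rather than assumed.
  Indices are 0-based with half-open windows.
* **Normalization.** Per volume and per modality, z-score over nonzero
  (brain) voxels; the background stays exactly 0. A standard deviation
  below 1e-8 yields a zero output instead of a division blow-up. (The
  source setup does not state a normalization; per-volume z-scoring is the
  common BraTS practice.)
* **Resampling.** `resample_slice` offers linear (order-1) and cubic
  (order-3 spline) interpolation on an endpoint-aligned grid, matching the
  guidance that linear interpolation is the right 2-grid-point filter and
  cubic the right 4-grid-point one. Identity sizes return inputs unchanged.
* **Split.** Seeded shuffle of patient ids, then partition — 235/50/50 for
  a 335-patient cohort. Splitting is always patient-level; slice-level
  splitting would leak near-duplicate neighbors between train and test.

## Architectures

All families are U-shaped encoder-decoders with `depth` 2×2 max-poolings
and 2× transposed-convolution upsamplings (default depth 4; 176 = 16·11
supports it), same-padding throughout, stage widths doubling from
`base_filters`, same-level skip concatenation, and a final 1×1 convolution
with sigmoid output. ReLU is used everywhere; biases are dropped before
batch normalization.

Inception blocks concatenate parallel branches and batch-normalize the
merge. Two kinds are placed by spatial-resolution level: the
large-kernel-heavy block (1×1/3×3/5×5/7×7 with filter split f/8, f/8, 3f/8,
3f/8) at levels 0–1 where maps are large, and the small-kernel-heavy block
(1×1/3×3/5×5 split f/4, f/2, f/4) deeper, mirrored on the decoder. The
split ratios are a free choice — only the large-versus-small dominance is
prescribed — and any allocation satisfying that ordering is accepted by
`BlockSpec`.

The separable families replace every k×k (k>1) convolution with a depthwise
pass followed by a 1×1 pointwise pass. They also enable, by default, a
residual-dense encoder connection: the output of the first convolution of
encoder block 0, max-pooled to the right resolution and 1×1-projected to
the right width, is added into the first convolution of every later encoder
block (`encoder_residual`, available to all families). An optional
full-scale skip mode concatenates resized encoder features from every level
into each decoder stage; the default is standard same-level skips, since
only shape contracts — not wiring diagrams — constrain this choice.

The slice classifier is a plain CNN: five 3×3 convolution stages with
filters base×(1, 2, 4, 8, 16) — 32/64/128/256/512 at the default base —
each with ReLU and 2×2 pooling, then global average pooling and four dense
layers ending in one sigmoid unit: nine weight layers (pooling layers are
not counted).

## Cost model

Multiplication counts for a stride-1 same-padded convolution on a P×Q map
(the model assumes square maps, P = Q, and counts multiplies only —
additions are excluded): standard Y1 = Uw·Uh·C·D·P², separable
Y2 = Uw·Uh·C·P² + C·D·P², ratio Y2/Y1 = 1/D + 1/(Uw·Uh), computed in exact
rational arithmetic. `count_multiplies` applies the same formulas per layer
of a built model (4·C·D·P² for the 2×2-stride-2 transposed convolution,
in·out for dense layers), and `describe` exposes the per-layer table.

## Training

* **Optimizer.** Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-8. The reference
  recipe — learning rate 1e-4, 200 epochs, batch size 25 — is the estimator
  default. No early stopping by default; an optional `stop_at_dice`
  halts once the epoch-mean training dice reaches a target.
* **Losses.** Soft dice loss (1 − (2Σpg + s)/(Σp + Σg + s)) for
  segmentation, with smoothing s = 1 during training for stability on empty
  masks and s = 0 in reported evaluation metrics; binary cross-entropy for
  the classifier.
* **Initialization.** Segmentation weights are drawn i.i.d. N(0, 0.01)
  (seeded), biases zero, batch-norm scale/shift at identity. The classifier
  defaults to Glorot-uniform: it has no batch normalization, and the tiny
  fixed-sigma draw makes its activations vanish across nine layers (to
  ~1e-7 by the fifth convolution), leaving training stuck at chance — the
  Gaussian scheme remains available via `init_scheme="normal"`.
* **Augmentation.** Horizontal/vertical flips, zoom drawn from
  [1−z, 1+z] with z = 0.10, shear drawn from [−0.2, 0.2], applied
  identically to image and mask; images are interpolated linearly, masks
  nearest-neighbor and re-binarized. All draws are seeded.
* **Input size.** Models are fed the 176×176 crop (the crop section above);
  the crop size is configurable, including back to 240.
* **Determinism.** The whole stack is numpy on a fixed seed: identical
  config and seed reproduce initialization, batch order, augmentation and
  therefore the entire per-epoch history bit for bit on one platform.
  Cross-platform BLAS differences are not asserted against.

The engine itself (`incunet.nn`) is a compact reverse-mode autodiff on
numpy arrays: im2col/BLAS convolutions, depthwise convolution,
2×2-stride-2 transposed convolution, max pooling, batch normalization
(batch statistics in training, running averages in evaluation, momentum
0.1), dense layers and Adam. Every layer's gradient is verified against
central differences at 1e-6 tolerance in the test suite.

## Evaluation and comparison tables

Metrics derive from one pooled confusion tally over all evaluated pixels
(per-slice averaging is available but not the default, matching the
one-number-per-model convention). Sigmoid outputs are thresholded at 0.5
before evaluation. A vacuous denominator (e.g. sensitivity on a tumor-free
set) is defined as 1.0 with a warning. Comparison tables report signed
percentage-point deltas, 100·(model − reference), rounded to two decimals;
signs are always kept, including for decreases.

## Phantom generator

The phantom is the package's study-conditions generator, not an anatomical
simulator. Each patient is an ellipsoidal brain (semi-axes 0.70 of the
half-width in-plane — chosen so the whole brain always fits the 176/240
centered crop with margin — and 0.95 of the half-depth) containing up to
three concentric spherical tumor regions (edema ⊃ core ⊃ enhancing, labels
2/1/4). Modality contrast encodes the imaging semantics the architectures
rely on: edema brighter than normal brain on T2 and FLAIR, the enhancing
rim brighter than the core on T1ce. Gaussian noise (σ = 0.02 by default,
on region means of order 0.4–0.95) is added inside the brain and clipped at
zero. The cohort sampler controls the fraction of tumor-bearing slices
(default 0.43, matching the class-imbalance figure of the mirrored dataset)
by sizing the tumor's slice extent, with ±10% patient-to-patient jitter,
and can produce tumor-free patients for classifier training. Everything is
deterministic given (spec, seed).

What the phantom does **not** model: real anatomy and texture, Rician MRI
noise, bias fields, multi-site intensity variation, irregular tumor shapes,
partial-volume effects. Tests passing on phantoms therefore establish that
the machinery is correct (shapes, gradients, invariants, convergence on
separable data) — not that the architectures reach any particular accuracy
on real BraTS data, which is explicitly out of scope.

## Problem sizes used in tests

The test suite and sanity gates run at desk scale, chosen as the smallest
sizes that still exercise every code path: 24×24 to 64×64 phantoms, depth-2
networks with 8 base filters, 20-slice overfit runs with Adam at 1e-3 and
at most 200 steps, and a 4-filter classifier. At these sizes each
segmentation family overfits its 20 phantom slices to training dice ≥ 0.9
well within the step budget, and the classifier separates tumor from
tumor-free slices to accuracy 1.0 within a few epochs.

## Known limitations

* 2D only; no 3D convolutions or volumetric context beyond slice gating.
* The "recurrent" naming of the inception families follows the lineage this
  implements; there is no unrolled recurrence — the residual-dense encoder
  connection is the only cross-stage extra wiring.
* The engine is CPU numpy: fine for desk-scale experiments, not for
  full-resolution 200-epoch training runs.
* Batch-norm statistics make predictions depend on training batch
  composition; running averages with momentum 0.1 need a reasonable number
  of steps to settle.
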