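# Methods

## Problem and scope

Acute ischemic stroke appears on diffusion-weighted (DWI) and FLAIR MRI as
hyperintense lesions. This package implements per-slice binary segmentation
of such lesions: a residual encoder-decoder convolutional network maps a
160×160 single-channel slice to a per-pixel lesion probability map, which is
thresholded and scored against an expert mask with the Dice coefficient
`2|A∩B| / (|A|+|B|)`.

The clinical datasets the design is based on are private (a hospital cohort)
or external (a public challenge dataset), so the package ships a phantom
generator that reproduces the *structural* properties the pipeline depends
on, and every stage — slice preparation, augmentation, training, evaluation
— is specified and tested against those phantoms. The headline Dice scores
reported on clinical data (85.43 local / 79.23 challenge / 68.19 U-Net
baseline) are not reproducible without that data and are not claimed or
targeted here; what the package verifies instead is the architecture
(row-for-row output schedule and exact parameter accounting), the data
arithmetic, the objective, and that the training loop actually learns on
phantom cohorts at desk scale.

## Network architecture

The network is U-shaped with three block types:

* **Transition block** (encoder, ×4 plus one in the bottleneck):
  3×3 convolution (stride 1, same padding) → batch norm → ReLU → 2×2
  max-pool stride 2. Halves the spatial dims; sets the channel count
  (32, 64, 128, 256, 512 along the encoder).
* **Residual block** (after every transition): pre-activation
  BN → ReLU → 1×1 conv → BN → ReLU → 3×3 conv, merged with the block input.
  The published output shapes double the channel count at every residual
  block (e.g. 80×80×32 in → 80×80×64 out), which an identity addition
  cannot produce, so the default merge is channel-wise **concatenation**;
  a projected-addition variant (1×1-conv shortcut to 2C channels) is
  retained as an option.
* **Bottleneck**: one more transition + residual pair (5×5×512 → 5×5×1024)
  followed by a 1×1 "compress" convolution down to 64 channels — the
  feature maps handed to the decoder — with dropout (rate 0.5 by default)
  after the compression.
* **Decoder** (×4): parameter-free 2× nearest-neighbour upsampling,
  concatenation with the matching transition-block output (skip
  connection), 3×3 convolution + ReLU. After the last decoder level: a 3×3
  convolution to 32 channels, a final 2× upsampling back to 160×160, and a
  1×1 convolution + sigmoid producing the probability map. The published
  table lists no skip connection after the final upsampling and two rows
  under the same "Conv 5" name; both are implemented literally.

### Block conventions and parameter reconciliation

The published layer table fixes every output shape but leaves four block
internals open: the merge mode, the width of the residual 1×1 convolution,
whether the compress step keeps a batch-norm layer, and convolution biases.
`BlockConvention` enumerates these; `reconcile_conventions()` computes each
convention's closed-form parameter totals and their distance to the
published counts. Findings, reproduced by the report at run time:

* Non-trainable parameters (batch-norm running means/variances, 2 per
  channel) total **5,952** exactly when the 1×1 width factor is 1.0 and the
  compress step has no BN: normalisation channels
  (32+64+128+256+512) + (64+128+256+512+1024) = 2,976, doubled. This is the
  default convention. (The published prose says the 1×1 conv "reduces
  depth" and the compress row includes BN; both readings are incompatible
  with the published 5,952 and are therefore overridden by the counts.)
* The published trainable total (6,465,153) is **not** reproduced by any
  enumerated table-consistent convention — the default yields 8,064,641.
  Whatever unlisted layer change produced the published figure is not
  recoverable from the table; the reconciliation report states every
  convention's distance instead of guessing. The per-layer audit
  compensates: the engine's allocated arrays must equal the closed-form
  k·k·C_in·C_out(+bias) / 2C-per-BN sums layer by layer, for every
  convention.

The reference U-Net baseline is pinned to the widely circulated community
topology (two biased 3×3 convolutions per level over a 64-128-256-512
ladder, 1024-wide bridge, upsample + 2×2 conv decoders, 2-filter
penultimate and 1-filter output convolutions, no normalisation): this is
the unique common variant whose total is exactly the published
**31,031,685**, with zero non-trainable parameters.

## Computational engine

No deep-learning framework is used: the models run on a compact NHWC
float32 layer library written on numpy (im2col convolution lowered to BLAS
matrix products, batch normalisation, 2×2 max-pooling, nearest-neighbour
upsampling, inverted dropout, sigmoid) with hand-derived reverse-mode
gradients and an Adam optimiser. Gradients of every layer and of the whole
network are validated against central finite differences in the test suite.
Weights are He-normal initialised (std √(2/fan_in)); convolution kernels
(not biases or BN parameters) carry an optional L2 penalty.

One deliberate deviation from a plain He init: the output 1×1 convolution's
bias starts at −2.0 (sigmoid ≈ 0.12) rather than 0. Lesions occupy ~1–3% of
pixels, and with a soft-Dice objective every background pixel retains a
positive gradient at any p>0, so from an unbiased start the first Adam
steps — whose per-logit swing grows with layer width — drive all logits
into sigmoid saturation before any discriminative feature exists, killing
training. Starting the head near the background prior (the standard remedy
for rare-foreground heads) removes the pathology; at the published width
this is the difference between converging in tens of steps and not
converging at all.

## Slice preparation

1. **Centering** — the foreground (pixels above 10% of the slice maximum)
   centroid is translated to the image centre, rounded to whole pixels,
   zero-filled; all-background slices pass through unchanged. Default is
   per-slice; a per-volume mode (one shift for all slices, computed from
   the mean slice) is available since the published description does not
   distinguish the two.
2. **Lesion-slice selection** — exactly the slices whose mask has ≥1
   positive pixel, ascending.
3. **Model space** — bilinear resampling of the image to 160×160, nearest
   neighbour for the mask (stays binary), then per-slice min-max
   normalisation to [0,1]; a constant slice maps to zeros. The published
   pipeline states the 160×160 conversion but no intensity rule; per-slice
   min-max is the simplest bounded choice for a sigmoid-output network.

Splitting is by subject (34/5/5 of 44 in the clinical design), seeded.

## Augmentation

Training: the four quarter-turn rotations of each slice and of its
left-right mirror — 8 samples per slice, the dihedral group of the square,
applied as pure index permutations (mask in lock-step, pixel multiset
preserved). Evaluation: identity + mirror, each counted as an independent
sample. This reproduces the published ledger: 560→4480 / 120→240 / 112→224
per modality, doubled for two modalities; 275×8×2 = 4400 for the challenge
cohort. "Flip" is taken as the left-right mirror (anatomically the natural
one for axial brain slices) and rotations as counter-clockwise; both
choices only relabel the generated set (it is closed under the group) but
are fixed for reproducible transform identifiers.

## Objective and training

Per-image soft Dice, averaged over the batch:

    S(t, p) = 1 − (2·Σ t·p + ε) / (Σ t + Σ p + ε),    L = (1/N) Σᵢ S(tᵢ, pᵢ)

with ε = 1 (keeps empty-vs-empty at loss 0). Optimiser: Adam, published
learning rate 1e-4, batch size 128 ("core size" is read as the mini-batch
size, since all filter counts are fixed by the layer table), L2 coefficient
1e-5 on convolution kernels, dropout 0.5 — the latter two unstated in the
publication and chosen mild and conventional. Early stopping monitors
held-out Dice (patience 10); the best-validation checkpoint is restored.

### Desk-scale preset

The published recipe targets GPU training of ~9,000 augmented slices for
thousands of steps. The test suite instead trains on a phantom cohort of
~128 training / 32 validation slices, batch 8, a handful of epochs, on one
CPU — a few hundred optimisation steps. Three settings are adapted for that
regime and shipped as the desk preset (`DESK_SCALE_OVERRIDES` plus a
`bn_momentum=0.9` convention): batch size 8; BN momentum 0.9, so the
running statistics used at evaluation converge within tens of steps; and a
learning rate of 3e-4 reached through a 32-step linear warmup. The warmup
matters for the same reason as the output-bias prior: Adam's earliest steps
move every weight by ±lr, and on the published-width layers an un-warmed
rate ≥3e-4 saturates the sigmoid head within a few steps and kills
training, while the published 1e-4 is stable but converges noticeably more
slowly at this step budget. Dropout is off in the preset (regularisation
has nothing to do in a 3–5-epoch run).

## Phantom cohorts

Each subject: a bright ellipse ("brain", semi-axes ≈ 0.35 of the image,
random sub-10% off-centre placement) over Gaussian-smoothed noise, plus one
hyperintense lesion with an ellipsoidal radius profile along the slice
axis, spanning a contiguous run of slices drawn uniformly from 12–24 (so
~18 lesion slices per subject, matching the clinical average). The in-plane
radius is floored at 1.2 px so the lesion-bearing slice count is exact by
construction. Two modalities share geometry; the second modality's lesion
contrast is scaled ×0.6 (DWI being the more conspicuous sequence) and noise
is drawn independently. Defaults: 60 slices, 160×160, lesion radius 6–16 px,
lesion contrast 0.45, noise σ 0.05, intensities float32, masks uint8.

What the phantoms do **not** emulate: MR physics, bias fields, partial
volume, multi-focal or non-convex lesions, registration error, skull/CSF
anatomy. A model that reaches high Dice on phantoms has demonstrated that
the pipeline and optimisation work end to end — not clinical performance.

## Evaluation conventions

* Probability > threshold (strict), default 0.5.
* Dice of two empty masks = 1.0; one empty = 0.0.
* Reports aggregate per slice (the published protocol evaluates 2-D maps);
  per-subject means are also emitted, and every report is produced both on
  the original slices and on the flip-expanded set, since the published
  account does not say which of the two its figures use.
* Every report carries a dataset provenance tag (`synthetic` for phantom
  runs) so desk-scale numbers cannot be mistaken for clinical results.

## Numerical and degenerate-input choices

* float32 arrays throughout the engine; loss arithmetic in float64.
* Sigmoid input clipped to ±30 (float32 exp safety).
* Max-pool ties resolve to the first maximum (argmax order); pooling
  requires even spatial dims, guaranteed by the divisibility check at
  construction (input divisible by 2^(levels+1)).
* Even-kernel convolutions (the U-Net 2×2 up-convs) pad asymmetrically,
  one extra row/column at bottom/right.
* Empty evaluation sets, empty batches, non-binary masks, out-of-range
  probabilities and shape mismatches raise typed errors rather than
  propagating garbage.

## Problem sizes used by the test suite

Architecture and parameter checks run at the published geometry (160×160,
4+1 levels). Training-dynamics tests use reduced variants (2 levels, 8 base
filters, 32×32) except the training-sanity check, which trains the
published architecture on a ~128/32-slice single-modality phantom cohort,
batch 8, for up to 5 epochs per seed with an early stop once held-out Dice
reaches 0.85 — sizes chosen so the whole suite stays a desk-scale run.

## Known limitations

* CPU-only and single-device; a full-size epoch on thousands of augmented
  slices is out of reach (and out of scope).
* Training memory scales with the batch: the im2col buffers cached for the
  backward pass cost roughly 100 MB per 160×160 slice in a training batch,
  so the published batch size of 128 assumes an accelerator-class memory
  budget — CPU runs should stay near the desk preset's batch of 8.
* The trainable-parameter discrepancy against the published total is
  documented, not resolved; no table-consistent convention reproduces it.
* BN statistics are per-batch only (no synchronised or frozen variants).
* The phantom generator's realism limits (above) bound what passing tests
  demonstrate about clinical data.
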