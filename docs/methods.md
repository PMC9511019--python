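# Methods

## Problem and model

`plantgrow` predicts the short-term future of a growing rosette plant at the
leaf level: given `p` historical top-view RGB frames `x_{i-p:i}` and their
leaf instance masks `m_{i-p:i}` (fixed time step, 4 h by convention), it
generates `q` future frames and masks

```
x̂_{i+1:i+q} = D_x( T( E_x(x_{i-p:i}) + E_m(m_{i-p:i}) ) )
m̂_{i+1:i+q} = D_m( T( E_x(x_{i-p:i}) + E_m(m_{i-p:i}) ) )
```

RGB prediction is treated as regression plus adversarial image generation;
mask prediction as per-pixel multi-class classification.  The two input
streams are encoded separately (images get three residual blocks, masks one —
masks are simpler) and summed element-wise at a quarter-resolution latent
(`H/4 × W/4 × 256` at full scale), on the assumption that appearance and leaf
identity are mutually informative.  The time-series unit `T` is a
convolutional-GRU seq2seq: the encoder `T_E` absorbs the `p` latent features
in time order; the decoder `T_D` starts from the encoder's final output and
autoregressively emits `q` future features, each feeding *both* decoder
heads.  Because the recurrence is length-agnostic, one trained weight set
serves any `(p, q)` protocol (2to1, 3to1, 3to2, ...) without retraining.

### ConvGRU cell

The update is the standard convolutional GRU,

```
z = σ(GN(Conv3([x, h])))          # update gate
r = σ(GN(Conv3([x, h])))          # reset gate
h~ = tanh(GN(Drop(Conv3([x, r⊙h]))))
h' = (1 − z) ⊙ h + z ⊙ h~
```

with 3×3 convolutions, GroupNorm (8 groups, fewer when the channel count is
small) and dropout (rate 0.2) on the candidate convolution during training
only.  Hidden states initialise to zero.  One cell layer each for `T_E` and
`T_D` by default (`gru_layers` is configurable).

### Losses

```
L      = λ_x L_x + λ_m L_m,      L_x = λ_MAE L_MAE + L_GAN
L_MAE  = (1/q) Σ_j mean|x̂_j − x_j|
L_GAN  = (1/q) Σ_j (Dis(x̂_j) − 1)²          (least-squares, generator)
L_Dis  = (1/q) Σ_j (Dis(x_j) − 1)² + (1/q) Σ_j Dis(x̂_j)²
L_m    = (1/q) Σ_j mean_pixels CE(softmax(m̂_j), m_j)
```

Defaults `λ_x = 1.5`, `λ_m = 1.0`, `λ_MAE = 100` (the best settings of the
weight sweeps).  Two normalisation choices deserve a note because they fix
scales rather than semantics:

* the L1 norm in `L_MAE` is normalised per pixel and channel (a mean absolute
  error).  An unnormalised sum over a 256×256×3 image would exceed the
  adversarial term by ~10⁵ and make a weight near 100 meaningless;
* `Dis(x)` for a *patch* discriminator is taken as the arithmetic mean of the
  sigmoid patch score map, so the squared terms above act on one scalar per
  frame; `L_m` averages the cross-entropy over pixels (compensated by `λ_m`).

The discriminator is a 4-stage strided 4×4-conv patch critic with
InstanceNorm and LeakyReLU; at 256×256 its penultimate feature map is 31×31
and the sigmoid score map 30×30.  The printed architecture keeps a sigmoid
output even under the least-squares objective, and we follow it; scores are
therefore bounded in (0,1), which also bounds `L_Dis ≤ 2` analytically.  The
image head's final convolution is linear (no BatchNorm/ReLU) and its output
is clamped to [0,1] at inference only — a bounded activation on the last
layer would otherwise fight the regression target, and clamping inside
training would zero the gradients.

Training follows: AdamW (betas 0.9/0.999, weight decay 0.01, both library
defaults as only the optimiser name and learning rate are prescribed),
learning rate 1e-4, batch 4, 200 epochs at full scale; discriminator and
generator alternate 1:1 per step, the discriminator seeing detached
generated frames.

## Time-series augmentations

**Temporal mixup** blends every frame of a window with its temporal
successor, `x_new = λ x_t + (1−λ) x_{t+1}`, with a *single* λ shared by all
frames of the window so the pseudo-sequence remains temporally consistent.
Masks are mixed in one-hot probability space (mixing integer labels is
meaningless) and the mask loss consumes the resulting soft targets.  λ is
drawn uniformly on [0,1] per window (the published examples show 0.25/0.5/
0.75 but no distribution; uniform is the simplest superset and is
configurable).  Because blended frames look unnatural, mixup is used *only*
to pretrain; finetuning then updates all layers on natural frames.  Mixed
windows supplement rather than replace the originals, and windows ending at
the last frame of a record (no successor) are skipped with a logged notice.

**Temporal copy-paste** composes entirely new plants offline:

1. *Collect.*  Per-leaf time-series tracks are extracted from existing
   records (per-frame bounding box, RGB patch, binary mask, padded by one
   pixel).  A track is kept only if, in every frame from emergence on, its
   visible mask is a single 8-connected component, stays off the image
   border, and retains ≥ 90 % (configurable) of its maximum area so far —
   leaves that are partially invisible or split by overlap cannot be
   recovered and are removed.
2. *Compose.*  One background is drawn per new plant and shared across all
   frames; each chosen track receives one rotation (uniform 0–360°) and one
   scale (uniform 0.8–1.2) applied to all its frames; tracks are pasted in
   emergence order so that track `j` carries label `j+1` and newer leaves
   occlude older ones (painter's rule).  The output mask is derived from the
   actual composited occlusion, and each new plant's emergence offsets are
   sampled and sorted so the label-follows-emergence convention holds.

The original background-cleaning step used interactive heal-selection
inpainting in external software; this package instead accepts a
user-supplied background directory or synthesises textured backgrounds — no
inpainting is implemented.  Whether pasted tracks keep their source timing
is not prescribed; here each track starts at a sampled emergence frame and
holds its final appearance once its source frames are exhausted.  The study
protocol generates 40 augmented plants, merged into the training split only.

## Synthetic data

The generator emulates the komatsuna-style acquisition the model targets:
60-frame sequences (one frame every 4 h), at most eight leaves, one plant
per image, leaves labelled 1..8 in emergence order.  Leaves are oriented
ellipses at phyllotactic azimuths (golden-angle spacing) around a jittered
centre, with a radial colour gradient, each growing by a fixed relative rate
per frame until a size cap; newer leaves are composited on top of older
ones, and the mask is painted in the same pass so it agrees exactly with the
rendered occlusion.  Leaf orientation is fixed per leaf: growing a fixed
ellipse about a fixed centre guarantees the rasterised footprint is
monotonically non-decreasing, which is the invariant the tests rely on;
per-frame re-orientation could transiently shrink the pixel footprint.
Backgrounds are low-frequency noise over soil/tray tones.

What this emulates: emergence order, monotone growth, occlusion layering,
temporal consistency, background variation.  What it does not: leaf shape
detail (venation, serration), lighting and shadows, perspective, plant
motion between frames, sensor noise.  Passing tests therefore demonstrate
that the pipeline's mechanics (shapes, losses, augmentation bookkeeping,
convergence) are correct, not that full-scale image quality on real data is
reproduced.

## Evaluation

PSNR (`10·log10(255²/MSE)` on the [0,255] scale, capped at 100 dB for
identical images), SSIM (Gaussian window 11, σ 1.5, L = 255 — the window
form is not prescribed; this choice is frozen and matched by an independent
oracle in the tests), and Dice micro-averaged over leaf classes 1..C−1 on a
0–100 scale, excluding background.  Mask PSNR/SSIM are computed on
deterministic fixed-palette renderings of the label masks (black background
plus eight maximally separated hues, shipped frozen), since applying image
metrics to categorical data requires a rendering convention.  The image-
and mask-row Dice columns of a report are the same mask-derived value by
construction, mirroring how they are reported.  Reports aggregate means over
all predicted frames of all test windows; splits are at the plant level and
a leak check asserts no test-plant frame enters a training window.

## Numerical substrate

The network runs on a small reverse-mode autodiff engine written on numpy
(`plantgrow.nn`): float32 tensors, im2col convolution, nearest-neighbour
upsampling, Batch/Group/Instance normalisation composed from differentiable
primitives, a fused softmax cross-entropy, and AdamW.  Every operation's
backward pass is verified against central finite differences, and the
ConvGRU cell against a scalar-loop reference.  Degenerate inputs are
handled explicitly: argmax ties break toward the lowest class index
(background-favouring), zero-MSE PSNR returns the cap, an all-background
Dice comparison returns 100 with a logged notice.

## Problem sizes

Full-scale training (256×256, 32/256 channels, 60-frame sequences, 200
epochs) is a multi-GPU, multi-hour job.  The package's own test and
acceptance runs use reduced sizes chosen to exercise every code path:
32–64 px images, 4–8 base / 8–16 latent channels, 2-plant training sets,
200–800 optimisation steps.  Desk-scale sequences are shortened to 30
frames with the per-frame growth rate doubled (0.04 → 0.08), so plants
still reach their full footprint by the end of the series — truncating a
60-frame schedule instead would leave leaves occupying ~1 % of the image
and make leaf-level evaluation vacuous.  Under these conditions the L1
term reliably drops by well over 50 % and the model reaches non-trivial
leaf Dice on a held-out plant.  `scripts/acceptance.py` runs this
desk-scale pipeline end to end (synthesis → copy-paste → mixup pretraining →
adversarial finetuning → 3to1/2to1/3to2 evaluation) and reports the
quantities it computes.

## Known limitations

* The exact ConvGRU variant of the original system is unpublished
  (supplementary material); the standard cell above is substituted.
* Checkpoints store model and discriminator weights but not optimiser
  moments; resuming restarts AdamW state.
* The adversarial game at desk scale is only smoke-tested for stability
  (bounded critic loss, finite terms), not for image-quality gains.
* Offline rotation augmentation applies one angle to a whole sequence with
  nearest-neighbour masks; very thin leaves can lose single-pixel slivers,
  which slightly perturbs emergence frames on tiny images.
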