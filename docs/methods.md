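# Methods

`renovol` implements an automated CT kidney volumetry pipeline for dogs:
preprocessing heuristics, a 3D transformer encoder-decoder segmentation
network trained with a combined dice + cross-entropy loss, connected-
component post-processing, voxel-count volumetry, method-agreement
statistics, and linear reference models for normal kidney volume. A
synthetic phantom generator supplies ground-truthed test data for every
stage, so the whole pipeline is buildable and verifiable without clinical
scans.

## Image model and conventions

Volumes are `(z, y, x)` grids of Hounsfield units with spacing `(x, y, z)`
in mm; axial index 0 is the most cranial slice. Loaders enforce this
canonical order from the NIfTI affine or, for DICOM series, from
`ImagePositionPatient` projected on the slice normal (never
`InstanceNumber`, which export order can scramble). Physical position of a
voxel is `origin + index * spacing`; label maps are unsigned 8-bit NIfTI
(at most four classes). For DICOM input, in-plane patient orientation is
not re-gridded — rows/columns map directly to the y/x axes — because only
slice order and spacing matter downstream.

Two contrast-phase label schemes exist: pre-contrast (background /
parenchyma / pelvis-and-fat) and post-contrast (background / cortex /
medulla / pelvis-and-fat). Renal parenchyma is always the union of the
cortex and medulla classes (or the single parenchyma class pre-contrast);
pelvis fat is labelled only so that segmentation does not absorb it into
the kidney.

## Preprocessing

Four steps, in order:

1. **Body crop.** Tightest axis-aligned box around all voxels above a
   background threshold. Default −900 HU: air in a noisy scan is centred on
   −1000 HU, so a cut exactly at −1000 would classify half of the air as
   body; −900 sits ten noise standard deviations above air yet far below
   aerated lung (≈ −800 HU). Exposed as a parameter.
2. **Kidney localization.** Canine kidneys lie just caudal to the lungs.
   Axial slices are scanned cranial→caudal; a slice is lung-containing when
   at least a fraction τ (default 0.05) of its in-body voxels fall below an
   air threshold (default −400 HU). The caudal margin is the last such
   slice; the crop spans a cranial margin (default 10 mm) plus a caudal
   window (default 120 mm) with the full in-plane body crop. The
   air-fraction statistic is this package's concrete operationalization of
   lung detection "by average intensity and histogram"; threshold, τ and
   margins are all parameters. If no slice qualifies, the pipeline logs a
   warning and falls back to the whole-body crop.
3. **Resampling** to fixed spacing (x = 1.5, y = 1.5, z = 2.0 mm),
   trilinear for images and nearest-neighbour for labels. The output grid is
   `round(extent / target)` voxels per axis (min 1), which preserves the
   physical extent within one voxel — and hence label volumes within a few
   percent for smooth structures.
4. **Intensity normalization.** HU clipped to [−1024, 3025], then to
   [−175, 250], then rescaled linearly to [0, 1]. The [0, 1] rescale is an
   addition beyond the clipping itself: the network needs a bounded input
   scale, and the map is affine and reversible. The function is idempotent
   (an already-normalized volume passes through unchanged).

## Segmentation network

A UNETR-style architecture: the encoder is a vision transformer over
non-overlapping 16³-voxel tokens (linear patch embedding plus a learned
positional table), with 12 pre-norm transformer blocks, hidden dimension
768, feed-forward dimension 3072 and 12 attention heads on a 96³ input
patch; one input channel and three output channels. The decoder has three
decoding stages, each two rounds of 3×3×3 convolution + batch norm + ReLU
followed by ×2 transposed-convolution upsampling, consuming skip features
tapped from evenly spaced encoder blocks (blocks 9, 6, 3 of 12, deepest
block feeding the coarsest level). Which encoder depths feed the skips is
not externally fixed; evenly spaced taps are this package's choice. A final
head upsamples to full resolution and fuses a convolutional feature map of
the raw input — giving the decoder direct access to full-resolution
intensity — before a 1×1×1 convolution produces class scores. The design
constrains `token_patch = 2^(stages+1)` so the decoder exactly restores the
input resolution (16 = 2⁴ for three stages plus the head).

The three output channels are background, cortex-or-parenchyma, and
medulla: pre-contrast parenchyma maps to channel 1 (channel 2 trained
empty), post-contrast pelvis-fat maps to background, and the parenchyma
probability/volume is always the union of channels 1 and 2 — so both
phases train one network and volumetry is phase-agnostic.

A **tiny preset** (64³ patch, hidden 96, feed-forward 384, 4 heads, 4
blocks, decoder channels 32/16/8/4) satisfies every structural invariant at
roughly 1.2 M parameters and is the configuration the test suite trains.

The network, its gradients and the optimizer are implemented on NumPy with
a small reverse-mode autodiff engine (`renovol.nn.autograd`): convolutions
are expressed as a channels-first im2col gather plus BLAS matrix
multiplication, and every primitive's gradient is pinned by central
finite-difference tests. One patch is processed per step (batch norm
statistics are over the spatial axes).

### Loss

`F = L_dice + L_CE`, unweighted — both terms live on a comparable scale.

* `L_dice = 1 − 2·Σ(t·p) / (Σt² + Σp² + ε)` with soft probabilities and
  ε = 1e-5, computed one-vs-rest per foreground class and averaged over
  classes non-empty in the target. The non-empty restriction is needed
  because ε appears only in the denominator: a correctly-empty channel
  would otherwise contribute a dice loss of 1 forever (relevant whenever
  channel 2 is unused pre-contrast), and a perfect prediction could never
  approach zero loss.
* `L_CE` is the mean per-voxel negative log probability of the true class,
  with probabilities floored at 1e-7.

### Training and inference

AdamW (decoupled weight decay 0.01) at initial learning rate 1e-5 over 400
epochs is the full-scale recipe, with linear warmup over the first 10 % of
steps and global gradient-norm clipping at 1.0 (cosine decay of the
learning rate is available but off by default: on the short schedules used
here most of the dice-plateau escape happens mid-run, and decaying the step
size afterwards truncates the refinement phase); each augmentation — random crop, random
flip, random rotation (90° multiples or ±10° about the axial axis), random
intensity shift (±0.1 on the normalized scale) — fires independently with
probability 0.1. Augmentation magnitudes are configurable; the listed
defaults are this package's choices. The checkpoint with the best
validation parenchyma DSC is kept (ties to the earlier epoch); the loss
curve is recorded per epoch and a non-finite loss aborts.

The scaled-down recipe used by the tests (`TrainConfig.tiny`) runs the tiny
preset for 30 epochs at learning rate 2e-3 on 12 noiseless phantoms with 4
held out: a ~1000× smaller model over a ~10× shorter schedule needs a
proportionally larger step size, and warmup plus clipping keep the larger
step stable. Everything else (loss, augmentation probabilities, checkpoint
rule) is unchanged. Convergence depth within the fixed 30-epoch budget
still varies with the initialization draw: typical runs reach held-out
parenchyma DSC 0.95+, hard draws land near 0.8, and with only four held-out
phantoms the volume-agreement CCC is correspondingly high-variance.

Inference is sliding-window with the training patch size, 50 % overlap and
uniform averaging of overlapping softmax outputs; volumes smaller than the
patch are zero-padded and cropped back. Labels are the per-voxel argmax
(ties to the lowest class id).

## Post-processing and volumetry

The predicted parenchyma mask is split into connected components
(26-connectivity by default; 6/18/26 selectable). At most four major
components are considered; among them the pair (default `expected = 2`,
bilateral kidneys) maximizing total voxel count subject to a minimum mutual
centroid separation (default 20 mm — prevents selecting two fragments of
one kidney) is retained and re-ordered by the canonical key (axial
position, then left-right). With a single kidney expected, or fewer
components than expected found, the largest are kept with a warning.
Post-processing can only remove foreground, never add it.

Volume is the voxel count times the voxel volume,
`x·y·z spacing × n_voxels`, reported in cm³ (mm³ internally). Reported
kidney volumes are the summed bilateral pair; per-component volumes are
available from the component set.

## Agreement statistics

* **DSC** `2TP/(2TP+FP+FN)`; two empty masks score 1 by convention
  (vacuous agreement, counted separately in reports).
* **Lin's CCC** with population (1/n) moments — the original estimator —
  and a 95 % CI from the Fisher z-transformation with Lin's asymptotic
  variance.
* **ICC(2,1)**: two-way random-effects, absolute-agreement, single-rater
  form, with the standard F-based interval; the two measurement methods are
  treated as random raters. The "absolute agreement" family admits several
  variants; ICC(2,1) is the conventional choice for two methods measuring
  the same cases once.
* **Mean difference index**: mean of `|truth − automated| / truth`.
* Pearson r for completeness.

The implementation is cross-checked in the tests against hand-computed
ANOVA mean squares and against an independent statistics package.

## Reference models

Four packaged linear models predict total kidney volume (cm³) in normal
dogs from body weight BW (kg), body condition score BCS (1–9) and age
(years), stored at their printed 3-decimal precision together with their
reported R²:

| model | equation | R² |
|---|---|---|
| bw | V = 3.701·BW + 11.962 | 0.74 |
| bw_bcs_index | V = 19.823·(BW/BCS) + 10.705 | 0.72 |
| bw_bcs | V = 3.740·BW − 1.071·BCS + 17.181 | 0.74 |
| bw_age | V = 3.697·BW − 0.054·age + 12.497 | 0.74 |

The BW/BCS index is read literally as body weight divided by body condition
score. The volume/BW index (volume divided by BW) normalizes volume across
dog sizes. For a dog with a measured volume the package reports the
measured/expected ratio; no clinical decision threshold is implied. New
models are fitted by OLS (coefficients, R², residual SD, p-values), and
fitted models can report an approximate 95 % prediction interval from the
residual SD — an extension of this package, not a packaged result.

## Phantom generator

The phantom is a geometric idealization carrying exactly the features the
pipeline depends on: an elliptic-cylinder soft-tissue torso (55 HU) in air
(−1000 HU), aerated lung (−800 HU) filling the cranial 30 % of the axial
extent, and two bilateral kidneys caudal to the lung margin, each a nest of
concentric ellipsoids — cortex shell (3 mm), medulla, pelvis-fat core
(35 % of the medulla's semi-axes). Tissue means: pre-contrast parenchyma
35 HU, post-contrast cortex 150 HU / medulla 100 HU, pelvis fat −90 HU —
standard tissue ranges, all configurable. A single additive Gaussian noise
field (default σ = 10 HU, a realistic abdominal-CT noise level) is applied
on top of the per-tissue means. Class membership is decided at the voxel
centre in physical coordinates, so every structure has an exact closed-form
volume (4/3·π·abc differences of concentric ellipsoids) as the volumetry
oracle; identical spec + seed gives bit-identical output.

The standard suite (`phantom_suite`) draws per-phantom kidney semi-axes
uniformly in [9, 14] mm (x, y) and [16, 24] mm (z) with a few mm of centre
jitter on a 96×96×64 grid at (1.5, 1.5, 2.0) mm spacing, so kidney volumes
genuinely vary across the suite — a prerequisite for correlation-style
agreement statistics.

The cohort generator draws body weight log-normal (mean ≈ 6.8 kg,
SD ≈ 5.4 kg, matching a small-breed hospital population), BCS mostly 4–6,
age from a clipped normal (9.3 ± 4.1 y), and kidney volume from a known
linear model plus Gaussian residual noise. The default generating model is
slope 3.701 cm³/kg, intercept 11.962 cm³, residual σ 11.8 cm³ — the σ that
makes the BW model explain ~74 % of the volume variance under this BW
distribution.

**What the phantoms do not model** — and hence what passing tests cannot
show about clinical data: realistic organ shape and tissue texture,
partial-volume effects, beam hardening and motion artifacts, contrast-phase
dynamics, anatomical variation beyond ellipsoid size/position, and
pathology. Phantom results validate the machinery (geometry, losses,
statistics, plumbing), not clinical segmentation accuracy.

## Numerical choices and degenerate inputs

* Dice ε = 1e-5; cross-entropy probability floor 1e-7.
* Softmax computed with max-subtraction; inference accumulates in float64.
* Network weights: truncated-normal-style 0.02 init for transformer
  projections, He init for convolutions; fully seeded (config seed).
* Resampling samples input index `j·target/spacing`, clamped at the edges.
* Argmax ties decode to the lowest class id; component-size ties break
  toward the lower minimum linear index.
* Degenerate agreement inputs: identical constant series make the CCC
  undefined (error); identical non-constant series return ICC 1 with a
  collapsed interval; an all-background crop raises rather than returning
  an empty box.
* Rotation by 90° multiples requires a square in-plane grid; otherwise the
  small-angle branch is used.

## Problem sizes in the test suite

The suite trains the tiny preset (not the full-scale configuration) on the
standard 96×96×64 phantom grid: 12 training / 4 validation phantoms for 30
epochs, the scaled-down analogue of the full training recipe. Localization
properties use a 20-seed suite; statistical oracles use fixed small series
plus 1000 randomized cases; cohort fits use n = 159–200. The acceptance
script repeats these computations from scratch with seeds derived from its
`--seed` argument.

## Known limitations

* The trained tiny model segments intensity-separable ellipsoids; no claim
  is made about clinical DSC levels.
* Left/right kidney naming is purely coordinate order, not anatomy.
* DICOM support covers plain axial series (no DICOM-RT, no networking).
* The full-scale (96³ patch, 768-hidden) configuration is buildable and
  runs forward on CPU, but training it is a GPU-scale undertaking outside
  the test suite's scope.
* The CCC confidence interval uses the asymptotic Fisher-z form; for n < 10
  it is indicative only.
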