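# Methods

This note documents the models implemented in `facerecon`, the synthetic
data they are exercised on, the numerical choices made where the design was
open, and what the desk-scale results do and do not show.

## The decoding framework

**Attribute network.** The feature extractor is a VGG-style stack of five
conv blocks (each conv–ReLU–conv–ReLU–maxpool) and two fully-connected
layers, ending in three heads of dimensions (7, N, 2) for expression,
identity and gender.  `split_index ∈ {0..7}` controls how many of the seven
units are shared before the three branches separate; all eight variants are
constructible, and a bookkeeping invariant (trunk parameters strictly
increasing, branch-exclusive parameters strictly decreasing in the split
index) is tested.  Training minimizes the convex combination
`α₁·CE_exp + α₂·CE_id + α₃·CE_gen` with SGD (default lr 0.001, momentum
0.9, batch 32), L2 of 1e-3 on the first FC of each branch and dropout 0.5 on
the second.  Because validation identities are disjoint from training
identities (open-set protocol), validation identity performance is measured
by pair verification: Euclidean distances between penultimate
identity-branch activations, a distance threshold selected per fold on the
other nine folds, ties broken toward the smallest threshold.  Same/different
pairs are sampled with replacement, since a small validation set does not
contain 900 distinct same-identity pairs.

The multi-dimensional face features are `z = (t_id, t_exp, t_gen)` with
`t_id` the post-ReLU penultimate identity-branch activations and
`t_exp`, `t_gen` the softmax head outputs.  This decomposition is chosen so
that the total dimension is `fc_width + 7 + 2` (521 at full scale) and the
two categorical blocks live in [0, 1], which the conditional GAN's BCE
targets require.

**Linear maps.** Each attribute block is regressed on the voxel responses
of its ROI group by the matrix normal equations `W = (SᵀS)⁻¹SᵀT`, jointly
over feature dimensions (equivalent to per-dimension OLS), with no
intercept.  If the design is rank-deficient (e.g., more voxels than stacked
training rows) the fit falls back to the minimum-norm pseudoinverse with a
warning; when SᵀS is invertible the two solutions coincide (tested).
Training stacks the selected runs as independent rows; prediction averages
the held-out runs — stacking maximizes training samples while averaging
minimizes test noise.  Both modes are exposed.  Predicted categorical blocks
are clipped into [0, 1] (with a warning) before entering the generator;
strategies that constrain only a subset of attributes zero the omitted
blocks of z.

**Conditional GAN.** The generator maps z through one (traditional) or two
(improved) fully-connected layers to a 4×4 feature map and a stack of
stride-2 transposed convolutions to a tanh image.  The discriminator is a
four-stage stride-2 conv trunk with a sigmoid realness head and, in improved
modes, three parallel sigmoid attribute heads.  The discriminator maximizes
`E[log D(x)] + E[log(1−D(G(z)))] − λ_D·Σ BCE` over the six attribute terms
(three heads × real/generated), λ_D = 20; the improved generator minimizes
`E[log(1−D(G(z)))] + λ_G·MAE(G(z), x)`, λ_G = 20.  One-sided label smoothing
sets the real-image target to 0.9; fake targets stay 0.  Identity features
are sigmoid-squashed to form BCE targets (softmax blocks already lie in
[0, 1]); a one-hot-target alternative is provided behind a flag.  The
optimizer is Adam (β₁ = 0.5), the DCGAN convention, since the original
description fixes only the batch size (16) and the λ's.

Two numerical choices matter at desk scale.  First, real images are
normalized to ±0.9 rather than ±1: the synthetic glyphs are high-contrast,
and an exact ±1 target sits at the tanh asymptote where the pixel-loss
gradient vanishes — without the headroom the generator collapses to the
mean image.  Reconstruction divides the headroom back out before rescaling
to 0–255.  Second, the pixel term is an L1 loss, whose per-pixel optimum is
a median; strokes that occupy a pixel for only one of seven expressions are
therefore suppressed in the early unconditional solution, and the
expression-conditioning pathway emerges only late in training.  The
conditioning test trains its toy model to convergence (several hundred
epochs) for this reason.

**Cross-subject alignment.** Each subject's stimulus × voxel matrix spans a
mean-centered PCA eigen-space (default k = 56, treated as a free parameter).
Responses of both subjects to shared stimuli determine an unconstrained
least-squares transform between eigen-spaces (an orthogonal-Procrustes
variant is available behind a flag).  The training subject's feature maps
are fitted on its eigen-coordinates — the smaller, better-conditioned
design — and prediction routes the test subject's coordinates through the
transform; regression on back-projected voxel responses is exposed as an
alternative mode.  When the two subjects are identical the transform is the
identity up to least-squares round-off, and the cross-subject prediction
reproduces the intra-subject one to 1e-8 (and bit-exactly after 8-bit image
quantization).

## Synthetic study conditions

The stimulus generator renders grayscale face glyphs on a configurable
canvas (64×64 by default; 32×32 in most tests).  Identity draws six
continuous shape parameters (face outline axes, eye spacing/height/size,
nose length) from a seeded standard normal; expression selects one of seven
equally spaced mouth-curvature levels and, through a fixed permutation so
the two cues are not collinear, one of seven eyebrow-angle levels; gender
(identity-index parity by default) controls jaw width and a hair band.
Rendering is a pure function of (parameters, seed) and bit-reproducible.

Ground-truth "indicator" features are the six identity parameters plus
one-hot expression and gender blocks.  ROI responses are simulated as
`response(run, stim, roi) = z·W_true(roi) + ε`, ε i.i.d. `N(0, noise_sd²)`
per run/stimulus/voxel, six ROIs × 56 voxels, five runs.  Selectivity is
realized by which feature blocks have nonzero rows in `W_true`: pSTS and
amygdala encode only expression; FFA and aIT only identity and gender; OFA
all blocks; V1 all blocks at half gain (a stand-in for weak low-level
attribute coding).  Weight SDs scale as `1/√block_dim` so each selective
block contributes about unit signal variance per voxel, and the default
`noise_sd = 1.0` therefore corresponds to a per-run signal-to-noise ratio
near one — a deliberately moderate regime in which three stacked training
runs still support reliable decoding.

What the simulator does *not* emulate: hemodynamics and GLM estimation,
voxel-to-voxel noise correlations, nonlinear or sub-additive attribute
coding, retinotopic/pixel-level V1 structure, and photorealistic face
variation.  Passing tests show that the pipeline recovers structure it is
built to recover under a known linear encoding — they are calibration and
correctness checks, not evidence about real brains or real faces.

## Evaluation statistics

MSE, PSNR and SSIM are computed on the 0–255 scale; SSIM uses global image
statistics (one window spanning the image), constants C₁ = (0.01·255)²,
C₂ = (0.03·255)² — the standard convention, configurable — with a
sliding-window variant behind a flag.  PSNR of identical images returns +inf
with a warning.

Both resampling statistics fix the predictions and redraw only the
distractors: repeat r uses seed + r, distractors are uniform per item
excluding the item's own ground truth, and exact ties count as failures
(conservative; ties have measure zero for continuous features but do occur
for duplicated categorical blocks — e.g., identity features repeated across
the seven expressions of one identity, which lowers the attainable ceiling
and shifts the effective chance level slightly below 50 %).  The one-sample
t-test against chance treats the repeats as independent observers, as the
procedure prescribes; because all repeats share one fixed prediction set,
that test is anticonservative under the null — the mean accuracy carries an
irreducible `√(1/12·n_items)` sampling component that distractor resampling
cannot average away.  Null-calibration tests therefore band the mean at ±3
of that exchangeable-null standard error and assess significance across
independent null draws.  FDR correction is Benjamini–Hochberg.

## Problem sizes

Desk-scale defaults mirror the study's structure at reduced width: 140 test
stimuli (20 identities × 7 expressions), 6 ROIs × 56 voxels, 5 runs with a
3-train/2-test split for seen-image decoding and 10-fold cross-validation
(126/14) for unseen-image decoding; networks use 32×32 inputs with
narrow channel stacks (attribute network ~8–32 channels, fc width 32;
generator base 32 channels).  The GAN ablation comparisons train each mode
for 50–60 epochs on ≤49 images across three seeds; these sizes were chosen
so a full experiment runs in minutes on one CPU core while leaving every
qualitative contrast (mode ordering, ROI selectivity, chance calibration)
resolvable.  Absolute accuracies from the original full-scale setting are
not reproduction targets at these sizes.

## Known limitations

- The numpy layer stack is float64 and CPU-bound; full-scale (512-wide,
  64×64+) training is out of reach, and no batch normalization is used.
- The adversarial terms are trained in their saturating printed form; at
  desk scale the MAE term dominates generator learning, and the traditional
  cGAN mode (no MAE) often stalls — which is also the regime in which the
  ablation ordering is measured.
- Expression classification of unseen identities at 32×32 is near chance
  for the small attribute network (the curvature cues span only a few
  pixels); gender and open-set identity separate well.  End-to-end
  experiments therefore default to indicator features, with the trained
  network's features as an option.
- `k = 56` eigen-dimensions and the ROI voxel count 56 coincide by
  construction, as in the setting emulated; both are configurable.
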