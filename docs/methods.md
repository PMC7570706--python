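# Methods

## Problem

Clinical movement assessment assigns an integer quality score to a short
video of a person performing a prescribed action (a walk, a sit-to-stand),
with 0 meaning normal execution and the maximum S depending on the movement
type (S = 4 or 5 for the walk variants, 5 or 12 for the sit-to-stand
variants modelled here). Cameras in the wild sit at arbitrary angles, so a
useful scorer must generalize across viewpoints it never saw in training.
The working hypothesis of this package is geometric: while the *appearance*
of a movement changes drastically with viewpoint, the 2D spatio-temporal
trajectories swept by body joints in the image plane are, to a good
approximation, affine transformations of each other across views. A
descriptor built from joint trajectories, normalized by a learned affine
transform, can therefore support view-invariant scoring.

## Pipeline

Input is per-frame 2D pose evidence for the first J = 15 joints of the
BODY-25 keypoint layout (head, neck, shoulders, elbows, wrists, mid-hip,
hips, knees, ankles), either as probability heatmaps or as keypoint
coordinates that we render into Gaussian heatmaps (peak at the joint,
amplitude equal to the detection confidence, sigma 2 px by default,
detections with confidence < 0.1 treated as missing). Videos are divided
into non-overlapping T = 16-frame clips; each joint contributes a
W x H x T heatmap stack per clip.

**Trajectory descriptor.** A single learned 3x3 2D convolution with T input
channels (stride 1, zero padding 1, then batch-norm and ReLU) collapses the
stack into one W x H map per joint — an image of where that joint's
probability mass travelled during the clip.

**Affine normalization (STN).** A small localisation network — conv 5x5 x10,
2x2 max-pool, ReLU, conv 5x5 (ch 10) x10, 2x2 max-pool, ReLU, FC(32), ReLU,
FC(4) — regresses a 2x2 matrix theta from each joint's descriptor. A
sampling grid is built over normalized pixel-center coordinates in
[-1, 1]^2 (origin at the map center) as source_i = theta @ g_i, and the
descriptor is resampled there by bilinear interpolation. The transform has
exactly 4 parameters: rotation/scale/shear about the center, no
translation. The final FC layer starts at the identity (zero weights, bias
(1,0,0,1)), so at initialization the transformer is a no-op and the
ablation (STN removed) is exactly equivalent. Samples falling outside the
input contribute zero, consistent with the zero background of trajectory
maps. Localisation weights are shared across joints (one transformer
applied per joint); theta is regressed per joint.

**Scoring.** The 15 view-normalized descriptors, each affinely rescaled to
the 0..255 image intensity range (a constant map rescales to zero, matching
the zero signal of a fully occluded joint), are stacked channel-wise and
classified into S+1 score classes by an image CNN whose first convolution
is re-channeled to 15 inputs and whose last FC layer has S+1 outputs.
Three families are provided: `tiny` (three conv blocks, coarse 4x4 average
pooling, two FC layers — the desk-scale default), `vgg19_adapted` (first
layer replaced by a 3x3, 15-channel convolution) and `resnext50_adapted`
(first layer replaced by a 7x7, 15-channel convolution + 3x3 max-pool);
middle layers follow the standard architectures. When 3-channel pretrained
first-layer weights are available they are tiled cyclically to 15 channels
and scaled by 3/15, preserving the response to constant inputs; otherwise
the adapted families initialize randomly.

**Training and video scoring.** One network per movement type, trained end
to end from scratch with plain SGD (lr 0.001, batch 5, 20 epochs), batches
drawn uniformly from the pooled clips of all training videos, softmax
cross-entropy on the clip's video-level score. At test time every clip of a
video is scored and the video's predicted score is
argmax_k (1/M) sum_m f_m(k) — the argmax over classes of clip-averaged
final-FC logits (not softmax probabilities), ties broken toward the lower
score. An alternative aggregation (maximum of per-clip argmax scores) is
available behind a flag but is not the default. Agreement over a test set
is summarized by Spearman's rank correlation with average ranks for ties.

## Differentiable engine

No GPU deep-learning framework is assumed: `viqa.nn` is a compact
reverse-mode autodiff engine on numpy float32 arrays implementing exactly
the ops the pipeline needs (conv2d with im2col and shift-and-add paths,
grouped convolution, max pooling, batch normalization, linear layers, ReLU,
bilinear grid sampling differentiable in both map and grid, adaptive
average pooling, fused softmax cross-entropy, plain SGD). Every op is
verified against central finite differences and scipy brute-force oracles
in the test suite. Batch-norm uses per-batch statistics in training and
running averages (momentum 0.1) in evaluation; a bypass switch exists so
oracle tests can check the raw convolution.

## Synthetic data generator

The generator stands in for a multi-view scored rehabilitation recording
set. It emulates the *structure* of such data, not its biomechanics:

- **Actions**: an articulated 15-joint stick figure performing a return
  walk (sinusoidal limb swing, one out-and-back root translation) or a
  sit-to-stand cycle (pelvis oscillating between seated and standing
  key-poses with trunk pitch).
- **Severity**: score s in 0..S maps to monotone kinematic proxies scaled
  by s/S — tremor amplitude up to 4 px at 5 Hz (per-joint random phase,
  distal joints weighted more), left/right amplitude deficit up to 0.5,
  cadence slowed up to 40%, stride shortened up to 45%, trunk lean up to
  20 degrees. Score 0 has zero tremor and zero asymmetry by construction,
  and a scalar severity statistic (high-pass tremor energy + stride
  asymmetry) increases strictly with the score at fixed seed.
- **Views**: 2D affine maps p -> A p + t with rotations in [-90, 90]
  degrees, anisotropic scales in [0.6, 1.4], shears in [-0.2, 0.2],
  approximating a ring of cameras; the first view is the canonical
  identity. Transformed sequences are re-centered into the frame.
- **Occlusion**: short-term (one contiguous run of ceil(fraction x n)
  frames, reflecting a few seconds of lost tracking) or long-term (the
  whole sequence) confidence drop-out on a chosen joint subset.
- **Subjects**: per-subject limb-length scale (normal, cv 10%, clipped to
  [0.75, 1.25]) and gait phase (uniform), constant across that subject's
  videos.

Durations default to 64–96 frames at a nominal 30 fps, inside the range of
real recordings of such actions. Everything is deterministic given the
config seed.

What the generator does *not* model: photorealism, 3D projective cameras
(views are strictly affine, i.e. the hypothesis is exactly true by
construction — real data only approximates it), pose-estimator noise
statistics, and any clinically calibrated distinction between adjacent
scores. Passing tests therefore demonstrate that the pipeline recovers
ordinal severity under affine view changes and occlusion at desk scale;
they do not certify performance on real patient video.

## Numerical and design choices

- Heatmap/descriptor resolution defaults to 56x56 (configurable).
  Experiment-scale runs in the test suite and the acceptance script use
  reduced maps so full training runs complete on a single CPU core: 32x32
  for the same-view experiment and 40x40 for the cross-view ablation,
  where the fidelity of the bilinear resample matters more (at 32x32 the
  resampling itself visibly degrades the warped descriptors). Videos are
  64–96 frames. The localisation network requires at least 16x16 input.
- Normalized grid coordinates use the align-corners convention (-1 and +1
  at border pixel centers), which makes the identity grid an exact
  identity map.
- The 0..255 rescale is applied to each view-normalized descriptor channel
  before stacking (a switch can disable it); its min/max scale factors are
  treated as constants in the backward pass, keeping gradients in plain
  affine form and avoiding the unstable derivative of a max.
- Trailing frames beyond the last full 16-frame clip are discarded rather
  than padded — padding would invent frames.
- Argmax ties in video scoring break to the lower score (conservative
  severity assignment, deterministic tests).
- No learning-rate schedule; constant lr 0.001.
- Per-fold training reseeds initialization with base_seed + fold index.
- Class balancing subsamples score-0 videos to a fixed count (15, or 4 for
  the high-resolution sit-stand scale) and augments minority scores with
  random temporal crops (contiguous, at least half the source length and at
  least 16 frames) until the per-score count ratio is bounded.
- k-fold cross-subject folds are built by partitioning shuffled subjects
  into k groups with k = number of distinct scores; test folds must
  contain at least two distinct scores.

## Known limitations

- Affine view changes cannot represent perspective foreshortening or
  self-occlusion geometry; the generator's long-/short-term drop-out is a
  crude stand-in for the latter.
- The severity mapping is a proxy, not a clinical model; absolute rank
  correlations on synthetic data do not transfer to real cohorts.
- The adapted VGG-19/ResNeXt-50 families are architecturally faithful but
  start from random weights unless a pretrained first-layer checkpoint is
  supplied; at desk scale the `tiny` family is the practical choice.
- With training data from a single view, the learned affine normalization
  improves cross-view transfer only modestly — consistent with the
  ablation pattern reported for this class of models — and the effect can
  be within seed noise for small synthetic sets.
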