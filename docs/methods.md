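# Methods

## Model

The package implements content-adaptive contrast generation as a
preprocessing block for grayscale image classification. The block has
two parts:

1. **Texture decision network.** Contrast selection is assumed to depend
   on local, high-frequency texture rather than semantics, so the
   network is deliberately shallow: conv 1→8 (3×3, stride 2, ReLU),
   conv 8→16 (3×3, stride 2, ReLU), global average pooling, and one
   fully connected layer 16→K. With K = 10 this is 1,418 parameters.
   The exact layer widths are a design choice of this package; the
   governing constraints were shallowness, texture sensitivity, and a
   small parameter budget (< 5,000).

2. **Bounded multi-view expansion.** The K raw outputs are mapped
   through `1 + 2·logistic(x)` into the clinical gain range and applied
   with the mean-preserving linear transform
   `α·(I − μ) + μ`, producing a K×H×W stack. The mapping's range is the
   *open* interval (1, 3) mathematically; in float64 the logistic
   saturates to the exact endpoints for |x| ≳ 37, which the tests treat
   as the representable closure of the open interval.

No clipping is applied anywhere in the transform path — values outside
[0, 1] are legal and keep the block differentiable; clipping to [0, 1]
happens only when views are exported as 8-bit rasters. Images load on a
canonical [0, 1] scale (8-bit inputs divided by 255); color inputs
collapse to grayscale by Rec. 601 luminance weighting. Transforms are
out of place. There is no diversity penalty among the K gains: collapse
to similar values is permitted and observable via the exported gain
sidecar.

## Differentiation

No autodiff framework is assumed; the two tiny networks run on a
minimal reverse-mode engine (`acam._autograd`) written for exactly the
operations needed (broadcast arithmetic, matmul, strided conv, ReLU,
logistic, reductions, softmax cross-entropy), in float64 throughout.
Correctness is established two ways: per-op central finite-difference
tests, and an end-to-end check (`numerical_gradient_check`) comparing
analytic gradients of a probe loss (sum of squared view pixels) against
central differences over sampled parameters and pixels; the maximum
relative discrepancy is required to be below 1e-3 at eps = 1e-4.

## Training modes

- **plain** — backbone on the raw image.
- **rcj** — random contrast jittering: one gain per image per epoch,
  uniform on [1, 3]. The range matches the adaptive block's output
  range; that equality is this package's assumption, made so the two
  approaches search the same gain space.
- **acam** — block and backbone trained jointly end to end (default
  integration).
- **acam_two_stage** — stage 1 regresses the *mean* of the K mapped
  gains onto the single recorded restoring gain α\* per image (one
  recorded value must supervise K outputs; the mean is the simplest
  unbiased reduction and leaves the per-view spread free), then the
  generator is frozen — bit-identical parameters thereafter — and only
  the backbone trains.

Classifier defaults follow the reference configuration: Adam, cross-
entropy, batch size 64, 20 epochs, learning rate 1e-3. Fixture-scale
runs in the tests use smaller batches (32), fewer samples (≈ 48–500)
and learning rate 3e-3, sizes chosen so the full suite runs on a single
CPU in minutes. Stage-1 defaults are 80 epochs at learning rate 1e-2:
the regression target is a scalar per image and the loss surface is
well conditioned, so the larger step is stable and the longer schedule
converges the held-out error well below the 0.15 acceptance bound
across dataset seeds.

Initialization: texture-net convolutions use seeded uniform weights of
scale 0.5 (texture features need usable magnitude from the start — with
very small conv weights the GAP features are ~1e-2 and stage-1
convergence stalls), the head uses scale 0.05 with zero biases so
initial pre-activations sit near 0 and initial gains near 2; the
backbone uses He-scaled normal init. All training is serial and
bit-reproducible under a fixed seed. No learning-rate schedule, weight
decay, or augmentation beyond the contrast modes is used.

The fusion default is channel stacking — the K-view stack is literally
the classifier input, so the backbone's first layer takes K channels.
Logit-mean fusion (backbone per view, class scores averaged) is
available for ablation.

## Synthetic phantoms

The generator emulates the *statistical nuisances* of operator-dependent
ultrasound, not its physics or anatomy:

- six geometric scene classes (ellipse + dark disc, elongated bar,
  V-wedge, two-lobed ellipse, ellipse + midline, blob field) with
  seeded position/size/orientation jitter;
- fully developed speckle: unit-mean exponential multiplicative noise,
  blended with strength 0.5 by default (one-parameter standard model);
- contrast compression with gain g drawn **log-uniformly on [1/3, 1]**,
  so the recorded restoring gain α\* = clip(1/g, 1, 3) is approximately
  uniform on [1, 3], matching the block's output range end to end;
- brightness jitter: one uniform offset in [−0.05, 0.05] per image;
- class proportions proportional to (711, 1040, 1626, 1718, 3092, 4213)
  — the imbalance profile of a six-class fetal-plane roster — rounded by
  deterministic largest-remainder apportionment;
- stratified 70/30 train/test split.

Before degradation each speckled scene is rescaled to a fixed reference
contrast (std 0.20 about its mean), emulating calibrated acoustic
output across acquisitions. This is what makes α\* identifiable from
image statistics — without a calibrated reference, scene-to-scene
contrast variation confounds the applied gain and stage-1 recovery is
ill-posed. Real clinical data carries no such calibration; stage-1
results on phantoms therefore demonstrate that the estimator recovers a
recoverable signal, not that clinical contrast records are this clean.
The statistical form of real operator variability is unknown; all
generator choices are explicit stand-ins.

For robustness studies the spec of a dataset can compress its test
split harder than its train split (`test_gain_range`), creating the
distribution shift under which the adaptive block should help.

What passing tests do **not** show: performance on real anatomy,
robustness to nuisances the generator omits (shadowing, probe-pressure
deformation, depth-dependent gain), or gains for large backbones.

## Numerical choices

- All core math in float64; invariant tolerances 1e-5 relative for
  mean preservation, 1e-6 for gain composition and variance scaling,
  1e-9 for mapping symmetry.
- Metric conventions: precision/recall/F1 are 0 when their denominator
  is 0; ROC ties get half credit (rank-sum equivalent); AP is the
  step-interpolated sum, not 11-point; aggregates are reported both
  macro and support-weighted (for single-label data, weighted recall
  equals accuracy — used as an internal identity check). ROC/PR curves
  and their areas are computed via scikit-learn, which implements
  exactly these conventions; the test suite cross-checks AUC against a
  brute-force rank-sum oracle to 1e-12.
- Largest-remainder apportionment breaks remainder ties toward the
  lower class index.
- Degenerate inputs: constant images are fixed points of every contrast
  transform (and of the whole block); images smaller than 8×8, non-
  finite pixels, non-positive gains and empty contrast vectors are
  rejected.

## Design decisions made where the design was open

- Estimator-shaped API: the method is fit/predict-shaped, so the public
  surface is scikit-learn estimators with thin manifest-level wrappers.
- Joint training is the default adaptive mode; the two-stage scheme is
  a separate mode, as it is an extension rather than the base method.
- Gain-range endpoints: the mapping is implemented as the open interval
  (1, 3) its closed form yields; attainable endpoints were not forced.
- Checkpoints are plain JSON (the networks are tiny and float64
  round-trips exactly through repr).
- Working resolution defaults to 64×64 (a configuration knob; nothing
  in the method depends on it).

## Known limitations

- The backbone is a deliberately small reference model; absolute
  accuracies on phantoms say nothing about state-of-the-art backbones.
- The number of views K is fixed per model; no variable-size or
  continuously parameterized contrast generation.
- No attention over gain regions and no nonlinear tone curves — the
  block is restricted to the linear mean-preserving family.
- Single-threaded numpy training: fine at fixture scale, not meant for
  datasets beyond a few thousand small images.
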