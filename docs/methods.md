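# Methods

This note documents the models, algorithms, and design choices behind
`cobbnet`: what is computed, under which assumptions, with which defaults,
and what the synthetic test bed can and cannot establish.

## Phantom spine model

Real ground truth for vertebral slopes is scarce: clinical radiographs
come with surgeons' Cobb angles at best, not per-vertebra endplate
orientations. The package therefore simulates radiographs of a physical
spine model with radio-opaque pedicle markers, for which the slope of
every vertebra is known by construction.

**Geometry.** Seventeen vertebrae (T1–T12, L1–L5) are placed at equally
spaced heights between y = 95 and y = 905 in a 1000-px-high image, with
body sizes growing superior→inferior (widths 68→96 px, heights 34→50 px).
The midline's lateral deviation x(y) is a sine arc — one half-period span
for a C-shaped `single_curve`, a full period for an S-shaped
`double_curve` — with a random phase shift (apex position) and tilt
direction. A vertebra's slope is the angle of its endplate versus
horizontal, equal to arctan(dx/dy) at its center; positive means the right
end sits higher on screen (image axes x right, y down). The two pedicle
markers sit symmetrically about the center along the endplate direction at
±0.25 × width, so the marker segment's angle *is* the slope.

**Slope distribution.** The configured magnitude range (default 5°–50°)
constrains the *maximum* |slope| of each spine: a smooth curve necessarily
passes through ~0° at its apex, so a per-vertebra lower bound would be
geometrically impossible. Each spine draws a target maximum slope
uniformly from an interval centered at a calibrated value μ; μ is found by
deterministic fixed-point iteration (quadrature over phases and targets)
so that the grand mean |slope| across spines and vertebrae equals the
configured mean (default 15°). A Monte-Carlo test over 10 000 spines
verifies both properties.

**Rendering.** Intensities are on the 8-bit scale: a smooth background
gradient (≈60–103), vertebral bodies as rotated rounded rectangles at
+80, darker endplate edges (−45 along the top and bottom 3 px of the
body), marker disks of radius 3 px at +150, a Gaussian blur of σ = 1 px,
then optional additive Gaussian noise (default σ = 5). All rendering
constants are invented — the point is a controllable image model whose
statistics (bright tilted body, small bright markers, soft edges, noise)
exercise the same pipeline stages as a real radiograph, not photorealism.
Images are rendered directly at the standard 1000-px height, so ground
truth is already in the standardized frame.

**Marker-based ground truth.** `detect_markers_and_slope` emulates how
slopes would be read off a physical model: threshold the window at its
99.5th intensity percentile, keep the two largest connected components,
and take the angle of the segment joining their centroids. A subpixel
refinement (squared intensity-above-(peak − 60) weighted centroid over an
11 × 11 box per blob) is applied because the raw top-percentile centroid
is biased by up to ~0.75° when a marker abuts the darker endplate edge;
with refinement the noise-free render→detect round trip is accurate to
better than 0.5° for all 17 vertebrae. Windows with fewer than two blobs
(or a third blob of comparable size) raise explicit errors rather than
guessing.

## Patch pipeline

Images are standardized to a height of exactly 1000 px (bilinear, aspect
preserved; already-standard images pass through untouched). Patches are
150 × 150-px crops — the window for center c spans [c − 75, c + 75) in
each axis, 0-based — reduced by a factor of three to 50 × 50. The
reduction is non-overlapping 3 × 3 block averaging: a three-fold
downsampling is the only reading under which 150 becomes 50 (three
successive halvings cannot). The 2500-vector is flattened row-major and
scaled to [0, 1]; bounded inputs keep the autoencoder pretraining stable.

Training patches are drawn with translation-only jitter: centers uniform
in a disk of radius 15 px around the vertebra center (100 patches per
vertebra in the reference protocol), each labeled with the vertebra's
*ground-truth* slope — labels never pass through the image, so image noise
cannot corrupt them. Draws whose window would leave the image are
redrawn; after 100 failures the vertebra is reported. Sampling is split
into a placement plan (`plan_patch_centers`, all randomness) and
materialization (`materialize_plan`, deterministic pixel extraction),
which also lets protocol arithmetic (e.g. 235 radiographs × 17 × 100 =
399 500 placements) be verified without holding four gigabytes of vectors
in memory.

## Slope network

The regression function is

A(P) = b₄ + W₄ tanh(b₃ + W₃ tanh(b₂ + W₂ (W₁ (P − b₁))))

read as mean-centering before projection: b₁ is the mean training patch
and the rows of W₁ are the leading 100 eigenvectors of the patch
covariance (computed exactly, by symmetric eigendecomposition of the
explicit 2500 × 2500 covariance; tests cross-check the subspace against an
independent SVD-based PCA). The first layer is a frozen low-pass filter:
fine-tuning updates layers 2–4 only, with an `unfreeze_pca` flag for
experimentation.

**Pretraining.** h2 and then h3 are initialized by single-hidden-layer
autoencoders (tanh encoder, linear decoder, squared-error loss, plain SGD
at learning rate 0.1 for each layer, 20 epochs, batch 128; decoders are
discarded). Raw PCA latents have component variances spanning orders of
magnitude, which SGD at a fixed 0.1 cannot handle, so each autoencoder
standardizes its inputs per component internally and the learned encoder
weights are rescaled back (W ← W/σ) afterwards — the initialized network
computes the exact composition above on raw latents; the standardization
is purely a conditioning device inside pretraining. This also leaves the
tanh layers operating on O(1) pre-activations at the start of
fine-tuning. The output layer starts small-random with b₄ set to the mean
training label. Pretraining the output layer itself (supervised) is
deliberately not done; only the two hidden layers are pretrained.

**Fine-tuning.** Plain mini-batch gradient descent on the mean squared
slope error, learning rate 0.01, batch 128, 50 epochs by default; labels
stay in degrees so training losses and evaluation errors are directly
interpretable as angles. All randomness (initialization, shuffling)
derives from the config seed; training is bit-reproducible. Defaults (h2
= 500, h3 = 50) match the reference architecture; (800, 100) and
(500, 250) are the studied alternatives and run under the same config
switch.

**Degenerate inputs.** The PCA layer refuses fewer than 101 patches (the
retained subspace would be rank-deficient); fine-tuning refuses unlabeled
patches, naming the offending patch's provenance.

## Cobb measurement

End-vertebra selection takes the maximum positive and minimum negative
predicted slope — equivalently, the opposite-sign pair maximizing
|sᵢ| + |sⱼ| (tests verify equivalence against exhaustive pair search).
Ties in |slope| resolve to the lowest index. Zeros are sign-neutral: a
flat vertebra may serve as either end, contributing 0°, and an all-zero
list yields 0°. If every clicked vertebra tilts the same strict way (the
user clicked half a curve), there is no opposite-sign pair: by default the
measurement returns the tilt span max(s) − min(s) with a `degenerate`
flag and a warning — still a meaningful quantity — while `strict=True`
raises instead. Inference is fully deterministic; permuting the clicks
permutes indices but never changes the angle.

## Reliability analysis

Agreement is ICC(2,1): two-way random effects, absolute agreement, single
measure, computed from the two-way ANOVA mean squares, with the 95% CI
from the F-distribution with Satterthwaite degrees of freedom. The
variant name is stamped into every report. With zero between-subject
variance the coefficient is undefined and reported as NaN, never as 0;
with literally perfect agreement (zero error and zero rater effects) the
estimate and CI collapse to 1. The implementation is cross-checked
against an independent statistical package's ICC(A,1) in the tests. MAD
is the mean absolute difference of paired measurements, in degrees.

Simulated examiners replace humans: in a session, every true vertebra
center is perturbed by isotropic Gaussian click noise (default sd 5 px at
1000-px image height — chosen as a plausible scatter for deliberate mouse
clicks on vertebral bodies ~40 px tall, and exposed in config) and the
full measurement pipeline runs on the perturbed clicks. Click placement
is the *only* source of variability, mirroring a system in which the user
merely assigns patches. Intraobserver studies repeat sessions with one
noise sd; interobserver studies may give each session its own sd
(experience differences are modeled as click scatter only — no attempt is
made to model human endplate judgment). Out-of-margin clicks are clamped
to the valid patch margin and logged.

## Study protocol sizes

The reference protocol (training on 235 radiographs × 17 vertebrae ×
100 patches = 399 500 patches) is validated at the placement-plan level.
Model training in the test suite and the acceptance script uses a
scaled-down protocol — 100 phantoms × 17 × 25 = 42 500 training patches,
evaluated on 680 centered patches (40 fresh phantoms × 17) — which trains
in a few minutes on a single CPU while leaving the evaluation protocol
(680 held-out patches) at full size. Reliability studies use 40 phantoms,
two sessions, 5-px click noise, averaged over 20 seeded replicates in the
acceptance script.

## What the phantoms do not show

Passing every test here demonstrates that the pipeline is correct and
that, *within the phantom image family*, slope regression and Cobb
measurement are accurate and highly repeatable. It does not establish
performance on in vivo radiographs: real images add ribs, pelvis, soft
tissue, exposure variation, anatomical variation between patients, and no
pedicle markers; a network trained on phantoms should be expected to
degrade substantially on such data, and training data from real
radiographs would be required. Marker detection is likewise only defined
for marker-bearing phantom images. The generator also varies pose purely
through the midline curve family — it does not model axial rotation,
vertebral wedging, or out-of-plane projection effects.

## Numerical notes

* PCA eigenvector signs are fixed (largest-magnitude loading positive) so
  fits are bit-reproducible across runs.
* Containers (`.npz` with a JSON header) round-trip weights bit-exactly;
  loaders validate shapes and the format tag and reject truncated files
  without returning partial objects.
* All random draws flow from explicit integer seeds through
  `numpy.random.Generator`/`SeedSequence`; there is no hidden global
  state, and CLI manifests record every seed used.
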