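# Methods

## Problem setting and model

`wsimil` predicts a binary molecular label (the motivating application is
IDH mutation status in infiltrating glioma) from an H&E whole-slide image
(WSI) using only slide-level supervision. A WSI is far too large for a
single network input, and patch-level labels do not exist, so the slide is
treated as a *bag* of patches under multiple-instance learning (MIL):

1. the slide is tiled into non-overlapping 256×256 patches at four nominal
   magnifications, 2.5×, 5×, 10× and 20×, realized as integer area-average
   downsamples of the base scan (40× base → factors 16/8/4/2);
2. an encoder f maps each patch to a D-dimensional embedding;
3. embeddings are aggregated by average pooling into one slide embedding;
4. a single affine + logistic head emits the slide probability (a
   "D-node fully connected classifier" is read as a D-input affine layer,
   not as an extra D→D hidden layer; the narrower reading keeps the head a
   pure linear probe on the bag embedding)

   p(slide) = σ( wᵀ · (1/n) Σᵢ f(xᵢ) + b ).

Mean pooling makes the bag prediction permutation-invariant and spreads the
slide-level gradient uniformly over patches, which is what makes weak
supervision trainable. A gated attention aggregator (softmax-normalized
convex weights over patches) is implemented as an optional inference mode
but is off by default; the training loop trains mean-pooling models only.

Separate models are trained per magnification and per random seed. At
inference, the three seed replicates of a scale are averaged into a
single-scale ensemble; the four single-scale ensembles are averaged into
the multi-scale ensemble (MSE); a patient's slides are averaged after
slide-level ensembling; and expert semiquantitative scores in [0, 1] can be
averaged with the MSE to form hybrid classifiers. Binary calls threshold at
0.5, with a score of exactly 0.5 called mutant.

## Tissue and artifact rules

A pixel is informative tissue when its greyscale value lies in the closed
band [40, 215]; brighter is background whitespace, darker is folded or
overstained tissue. Greyscale uses ITU-R 601 luminance
(0.299 R + 0.587 G + 0.114 B), rounded to the nearest integer; both the
weights and the band are configurable because the conversion convention is
a genuine free choice. A training tile qualifies when strictly more than
75% of its pixels are tissue. Heatmap windows use a looser strictly-more-
than-50% gate.

Pen-mark and blur exclusions have no canonical published thresholds, so the
defaults here are this package's own documented choices: a patch is
pen-marked when more than 2% of pixels have HSV saturation above 0.8 with
hue in a blue/green/red marker band, and blurred when the variance of a 3×3
Laplacian of the greyscale plane falls below 10. Both are configurable in
`ArtifactConfig` and can be disabled.

## Augmentation

Color jitter is applied at slide level: because one mini-batch is one
slide, a single draw of channel-wise HSV affine parameters
αc ~ U(1−σ, 1+σ), βc ~ U(−σ, σ) (σ = 0.05) is shared by every patch of the
batch, emulating slide-to-slide staining variation. HSV channels are
normalized to [0, 1]; values are clipped back to [0, 1] after the affine
map (an optional flag wraps hue circularly instead). Each patch is also
independently flipped with probability 1/2 (vertical or horizontal,
equiprobable) and rotated by a uniform multiple of 90°. Augmentation is
training-only.

## Training protocol

One optimizer step consumes one slide: up to 200 qualifying patches are
sampled without replacement (all of them if fewer exist), augmented, and
pushed through the bag; Adam minimizes the binary cross-entropy of the
slide probability. Epochs are class-balanced: all slides of the minority
class (paper-faithful count 140) plus an equally sized fresh sample of the
majority class, shuffled. When a dataset is smaller than the nominal
140/140, the per-class count shrinks to the smallest class, preserving the
1:1 ratio rather than the absolute counts. After each epoch the mean
validation BCE is computed without augmentation on all qualifying patches
per slide, deterministically capped at 500 per slide; the checkpoint with
the lowest validation loss is kept, earliest epoch winning ties. Training
aborts on a non-finite validation loss. Replicate seeds default to
{0, 1, 2}.

Paper-faithful hyperparameters (learning rate 1e-5, ≤100 epochs, 1024-wide
embeddings) are the `TrainConfig` defaults. The encoder is pluggable; the
default `tiny_cnn` backbone is a compact network — a 4×4 mean-pool stem
followed by four 3×3 conv/ReLU/2×2-pool blocks and global average pooling —
implemented, together with its backpropagation and Adam, directly on numpy
arrays (`wsimil.nn`) and verified against finite-difference gradients in
the test suite. Its default width is 64 (32 in the desk studies). Wider
ImageNet-style backbones can be registered without touching the MIL
contract.

## Numerical choices

- The bag mean (and the attention-weighted sum) accumulates rows in a
  canonical sorted order, making slide predictions bitwise invariant to
  patch order rather than merely close.
- RGB↔HSV conversion follows the matplotlib convention but is compiled
  with numba; the identity augmentation (α = 1, β = 0) short-circuits, so
  σ = 0 is the exact identity.
- Heatmap accumulation keeps an exact per-pixel running sum and window
  count; pixel values are undefined (NaN) where no window contributed.
  Cross-scale difference maps upsample the coarser raster to the finer grid
  by nearest neighbor and are defined only on joint coverage.
- All randomness flows from explicit integer seeds through named
  `numpy.random.Generator` substreams; identical configuration and seed
  reproduce prediction tables and evaluation reports byte for byte.
- AUC uses the Mann–Whitney midrank formula (equivalent to trapezoidal ROC
  integration); bootstrap CIs are percentile intervals over 1000 pair
  resamples, redrawing resamples that lose a class. A stratified resampling
  flag exists but is off by default, since plain pair resampling is the
  stated protocol.

## Synthetic cohorts

The generator writes flat-dialect slides (one raster plane + JSON sidecar
with slide/patient/label/magnification, plus a cohort manifest CSV). A
slide is a flat eosin-pink base whose luminance is modulated by a smooth
"cellularity" field (σ ≈ 8 grey levels, correlation length ~16 px), fine
per-pixel speckle (σ = 14), and planted class signal; tissue channels are
clipped so tissue luminance stays strictly inside [40, 215] while
background is exactly 255. Pen strokes are saturated marker-colored discs
whose greyscale still lies inside the tissue band — only the pen rule can
reject them; blur artifacts are Gaussian-smoothed regions.

The planted `blob_density` signal multiplies the expected count of bright
"microcyst-like" blobs by (1 + effect_size) in class 1. The luminance
modulation is re-centered per slide, so the signal is textural rather than
a slide-mean brightness offset (which would survive any downsample and
defeat scale specificity). Slides also carry label-independent per-slide
nuisances — a staining tint (σ = 6 per RGB channel), jittered cellularity
and speckle amplitudes, jittered blob radii, and a medium-scale luminance
field (correlation ≈ 128 px, amplitude 3) — because a cohort whose
embeddings vary along a single axis is degenerate: every random projection
would align with the signal and null controls could never sit at chance.
Scale dependence comes from blob geometry against the fine speckle:

- `coarse` — smooth Gaussian bumps (radius 48 base px, contrast 16). The
  only image content that area-downsampling removes is high-frequency
  noise, so this is the one honest scale asymmetry available: under heavy
  speckle (the planted-signal studies use σ = 24) the per-pixel
  signal-to-noise is ~0.7 at native 20× but ~5 after the 8× area-average
  to 2.5×, where one patch additionally sees the whole density pattern.
- `fine` — small hard-edged discs (radius 4, contrast 40), resolvable at
  high magnification and washed toward the noise floor at low power.
- `both` — intermediate (radius 16, contrast 18).

A `color_shift` signal type (class-dependent tint) and per-"lab" HSV batch
effects reuse the augmentation machinery with fixed draws. Synthetic expert
scores are logistic transforms of the label signal plus a shared
case-difficulty term (controlling inter-rater correlation) and private
noise, giving tunable rater accuracy and agreement.

What the generator does *not* emulate: real nuclear morphology, stain
chemistry, scanner optics, or spatially correlated diagnostic structures.
Passing the simulation studies therefore demonstrates that the pipeline's
machinery — tiling, masking, weak supervision, ensembling, statistics — is
correct and that scale-matched signals behave as designed; it does not
certify clinical performance on real slides.

## Desk-scale study protocol

`wsimil.studies` fixes the simulation conditions used by the test suite and
`scripts/acceptance.py`: a 70-patient one-slide-per-patient cohort
(2048-pixel base planes at nominal 20×, exact 35/35 class split), split
patient-disjointly into 40 train / 10 validation / 20 test slides with
balanced validation and test sets; the compact backbone (width 32) trained
for 6 epochs at learning rate 3e-3; coarse signal at effect size 3 under
speckle σ = 24. The effect size and geometry were chosen so that the
magnification matched to the signal recovers the labels (held-out
AUC ≥ 0.9) under these conditions. At this small step budget (~240
optimizer updates) a minority of initializations never escape the ln 2
loss plateau; a study arm whose selected checkpoint cannot rank its own
training-side slides (AUC over the pooled train + validation slides below
0.7) is therefore declared stalled and restarted once with a fresh
initialization — a rule that sees only training-side data and leaves
first-attempt successes bitwise unchanged. The null control below
deliberately runs without this rule, since failing to learn is its
expected behavior. The label-permuted control trains at
the matched scale on permuted labels of a matched cohort generated with
effect size 0, reporting the mean over three (permutation, initialization)
replicates scored against the true labels. The control cohort carries no
signal on purpose: a compact network trained for a few hundred steps
barely leaves its initialization, and on a cohort with a strong planted
feature the initialization's arbitrary projection of that feature still
ranks slides (with a random sign), so a permuted control run there
measures the initialization rather than the pipeline. With no signal
present the classes are exchangeable by construction and the classical
permutation distribution, centered at 1/2, applies. The 20× arm of the
scale comparison is reported with the caveat that its deficit relative to
2.5× is real but thin at these problem sizes. The hybrid-synergy
study is score-level: expert and "model" scores are simulated with
independent noise at equal signal-to-noise (AUC ≈ 0.85 each) over 20
replicates of 200 slides. Bootstrap calibration draws 200 binormal datasets
(50 + 50, true AUC Φ(1/√2) ≈ 0.76) and counts 95%-CI coverage.

## Known limitations

- No out-of-core WSI reading: a slide's base plane is held in memory, which
  is appropriate for synthetic and desk-scale slides but not gigapixel
  clinical scans; swapping in an openslide-backed reader only requires
  reimplementing `Slide.plane`.
- The attention aggregator is inference-only; training it would need
  backpropagation through the gating network.
- Downsampling supports integer magnification ratios only; non-integer
  pyramid levels would need interpolating resampling.
- Bootstrap CIs resample slides (or patients at patient level); no
  hierarchical slide-within-patient resampling.
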