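# Methods

## Problem

Sarcopenia in cirrhotic patients is diagnosed from the skeletal-muscle
cross-sectional area at the third lumbar vertebra (L3), normalized by
squared body height (L3SMI, cm²/m²).  When ascites compresses the
abdominal wall, the total-muscle measurement becomes unreliable, which
motivates segmenting the L3 musculature into four regions — Rectus
Abdominis (anterior wall group), Right/Left Psoas, Paravertebral — and
analysing each region's index separately.  This package implements the
full chain: synthetic CT phantoms for testing, preprocessing,
segmentation network (LSMU-Net), training harness, surface/overlap
metrics, and the downstream index/ROC analysis.

## Network

The input is one preprocessed L3 slab, a `1×1×8×H×W` tensor.  The
architecture has two coupled streams:

**2.5D backbone.**  The eight axial slices are permuted into the batch
axis (`8×1×H×W`) and processed by a 2-D residual U-Net: five `Block2D`
encoder stages of widths (8, 16, 32, 64, 128) with four 2× max-poolings,
then four decoder stages of nearest-neighbour 2× upsampling, skip
concatenation and `Block2D` at widths (64, 32, 16, 32).

**3D encoding branch.**  Three layers, each of (2× max-pooling over all
three axes, `Block3D`, texture attention enhancement) at widths
(16, 32, 64), operating on the intact volume so the sagittal/coronal
continuity of muscle-fibre bundles can resolve ambiguous axial
boundaries.  Depth shrinks 8 → 4 → 2 → 1 across the layers.

**Blocks.**  A *basic block* is 3×3(/3×3×3) convolution → InstanceNorm
(learnable affine) → LeakyReLU (slope 0.01).  `Block2D` is a
channel-transition basic block followed by a two-block residual group
(3 convolutions); `Block3D` uses a three-block residual group
(4 convolutions), giving the volumetric stream extra capacity.  The
residual addition is removed in the `nores` ablation.  Convolutions use
'same' zero padding, stride 1, Kaiming fan-in initialization with a
config-held seed.

**Texture attention enhancement.**  For a branch feature `x`
(`C×D'×H'×W'`): (i) SE-style channel weights
`s = σ(FC_C(ReLU(FC_{C/16}(GAP(x)))))`; (ii) pixel weights
`a = p(1−p)` with `p = σ(x)` — a map that peaks at 0.25 where the
activation probability is 0.5, i.e. at uncertain edge voxels, and
vanishes at saturated ones; (iii) the enhanced feature is the additive
combination `x⊙s + x⊙a`.  A squeeze-and-upsample step (mean over depth,
bilinear in-plane resize to `H×W`, channel-preserving 1×1 convolution)
and an 8× batch duplication produce the rank-4 fusion contribution.
The `se` ablation keeps only `x⊙s`; `noattn` passes `x` through.

**Fusion.**  Decoder-final feature (32 ch) + a 1×1 projection of the
first encoder feature (8 ch) + the three branch contributions
(16+32+64 = 112 ch) concatenate to 152 channels; a final 1×1 convolution
yields `8×5×H×W` class scores.  The 112/152 totals are construction-time
invariants; `NetworkConfig.scaled(k)` divides every width by `k` while
preserving the ratios for desk-scale runs.

Design points the printed totals do not pin down, resolved here: the
fusion split is 32 (decoder) + 8 (projected skip); decoder widths are
(64, 32, 16, 32), mirroring the encoder except for the last stage which
is widened to meet the 32-channel fusion contribution; the 3-D branch
pools depth together with the in-plane axes because a depth of 8 admits
exactly the three halvings of the three-layer design; channel and pixel
attention combine additively; the SE bottleneck is `max(1, C/16)` with
biases enabled.

### Differentiation backend

The network is a pure functional numpy implementation (channels-last
feature maps, convolutions as sums of shifted BLAS matmuls with
hand-written vector-Jacobian products) differentiated with `autograd`.
Forward passes on plain arrays are deterministic; there are no
stochastic layers.

## Loss

`Loss = Loss_ce + Loss_dice`, both class-weighted and written as sums
over the pixels of one axial image, averaged over the 8 batch slices so
the magnitude is depth-independent.  Class weights are prior statistics
of the training fold: `ω_c = 1 − N_c/(H·W·D·n) − offset_c` with
`offset = 0.2` for the two large muscle regions (classes 1, 4) and 0 for
the psoas classes (2, 3); the background uses the no-offset branch,
which — being the largest region — gives it the smallest weight.  A
weight ≤ 0 (class occupying more than `1 − offset` of all pixels) is an
error.  The soft Dice term uses ε = 1e−5 in numerator and denominator so
a class absent from both prediction and target contributes exactly 0.
Padded slices participate in the loss as background (the network trains
on the full padded block); they are excluded from all evaluation metrics
and indices.

## Preprocessing

Per-volume min/max normalization to [0, 1] over the full dynamic range
(constant volumes map to zeros with a warning), then zero-padding
appended at the end of the axial stack to depth 8.  Normalization
precedes padding, so padded voxels hold 0, the post-normalization
minimum.  `n_true_slices` is carried through all containers.

## Metrics

Per muscle class over the true slices only: DSC `2TP/(2TP+FP+FN)`,
Sensitivity `TP/(TP+FN)`, and ASSD — surfaces are mask voxels with at
least one face-adjacent (6-connectivity) non-mask neighbour; both
directed nearest-neighbour distance sums (exact Euclidean distance
transform with anisotropic spacing, millimetres) are divided by
`N_S + N_G`.  Conventions: a class empty in both masks scores DSC 1 and
ASSD 0; a class empty in exactly one mask has undefined ASSD (reported
missing, with a warning, and excluded from averages).  Cohort
aggregation reports mean ± sd (population sd).

## Training protocol

Stratified split (cirrhotic flag) into training and independent test
groups, stratified k-fold cross-validation inside the training group,
Adam at a constant lr 0.001 for a fixed epoch count, batch = one padded
volume (its 8 slices as batch elements), no data augmentation.  Loss
weights come from each fold's training portion only.  "Best model" =
highest final-epoch validation mean DSC over the four muscle classes,
ties to the lowest fold index; that model runs on the independent test
group.

## Phantom generator

Each phantom is an elliptical torso (axis-aligned, ~0.40H × 0.45W
semi-axes) with: a subcutaneous fat rim; a bright vertebral body
(posterior centre, bone ≈ 350 HU, labelled background); an anterior
muscle-wall ring (class 1) spanning ±115° from the anterior direction;
two psoas ellipses flanking the vertebra (classes 2/3; patient right =
image left); and a posterior paravertebral mass (class 4).  Tissue means
(HU): air −1000, fat −100, organ +20, muscle +48, bone +350, with
per-tissue texture noise, a σ = 0.6 px in-plane blur for partial-volume
softening, and additive acquisition noise (σ = 10 HU).  Region centres
drift linearly through the slice stack and psoas/paravertebral bodies
taper, so the volume has genuine 3-D structure for the 3-D branch to
exploit.  Label geometry is a deterministic function of the parameters;
the seed drives image noise only — this keeps cohort-level contracts
(identical geometry under zero jitter) exact.

Cohorts jitter torso/region scales (±6 %/±12 %), heights (1.50–1.90 m),
slice counts (4–8) and assign exact cirrhotic/female counts via seeded
permutations; cirrhotic patients draw a Rectus-Abdominis squeeze factor
from (0.15, 0.55) — modelling ascites compression — versus (0, 0.10)
for controls.  Per-patient seeds are `seed + index`.

What the phantom does **not** model: organ-level anatomy, fat
compartments, realistic CT noise spectra/artefacts, inter-individual
shape variability beyond affine-ish jitter, or any claim about the
intensity distribution of clinical scanners.  Passing tests therefore
demonstrate that the pipeline's machinery is correct and trainable, not
that clinical-grade accuracy is achieved on real CT.

## Indices and ROC analysis

Mean cross-sectional area per region = voxel count over true slices /
`n_true_slices` × pixel area (cm²); indices divide by height² (TPI sums
both psoas areas first; L3SMI uses the four-region total).  Diagnosis:
sarcopenia iff L3SMI < 50 (male) / 39 (female) cm²/m²; a value exactly
at the cut-off is non-sarcopenic (cut-offs are lower bounds of normal).
Correlations are Pearson, reported per group (sarcopenia status, sex,
all).  Regional cut-offs are derived from the ROC over midpoint
thresholds between sorted unique values, maximizing Youden's J (ties to
the lower cut-off), with trapezoidal AUC (equal to the normalized
Mann–Whitney U statistic; an independent identity used in the tests).

## Problem sizes and numerical choices

Desk-scale experiments use 8×64×64 phantoms (in-plane spacing scaled to
5.6 mm so the field of view matches a 512-grid at 0.7 mm) and a
width-factor-2 network (fusion 76 = 152/2), 24 patients, 3 folds,
10 epochs — chosen so a full study runs in minutes on one CPU while
preserving every structural invariant of the full-width design.  The
full-width network builds and runs forward at 8×512×512.  Training is
float32; loss-formula tests run in float64 against brute-force oracles
at 1e−9..1e−10 tolerances.  Dice ε = 1e−5, InstanceNorm ε = 1e−5,
argmax ties break to the lowest class index.

## Known limitations

* No automatic L3 localization — the package consumes pre-extracted L3
  slabs (or an explicit slice range via the CLI).
* `autograd`-based training is CPU-bound and 1–2 orders of magnitude
  slower than a GPU framework; full-width 512² training is out of
  desk-scale reach, though inference is practical.
* The empty-class ASSD convention (exclude + warn) makes cohort averages
  over degenerate segmentations slightly optimistic.
* Phantom realism limits, as above.
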