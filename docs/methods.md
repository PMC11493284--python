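# Methods

This note documents the models, numerical conventions and design
choices behind `nativecam`, and what the synthetic validation does and
does not demonstrate.

## Native-space philosophy

Every scan stays in its own scanner frame throughout. The price is that
voxel coordinates are not comparable across subjects; the pipeline pays
it once, at the region-attribution step, by transporting each subject's
anatomical parcellation onto that subject's attention grid through
affine algebra alone. With A the 4×4 voxel-to-world affine of the
attention grid and B the inverse of the parcellation's affine, an
attention voxel index Y maps to the parcellation index X = B·A·Y,
rounded to the nearest voxel (0.5 rounds toward +∞ per axis, a
deterministic tie-break at cell boundaries; out-of-field voxels become
background 0). Nearest-neighbour assignment is mandatory for labels:
linear interpolation would average category codes.

## Preprocessing

Stage order is resample → RAS+ reorientation → percentile clipping →
z-score → crop/pad. Geometry is fixed before intensities, and all
intensity statistics are computed before zero-padding so padding cannot
shift them. Conventions:

- Resampling preserves the world origin and covers the input field of
  view: `out_dim = ceil(in_dim · in_spacing / out_spacing)` per axis;
  linear interpolation with edge clamping (a constant image stays
  constant to machine precision).
- Percentiles (clipping bounds, the attention median, the RF selection
  threshold) all use linear interpolation between order statistics.
- The z-score uses the population (ddof 0) standard deviation over all
  voxels; a `zscore_nonzero_only` switch restricts the statistics to
  nonzero voxels for brain-extracted data. A constant volume is an
  error, never a silent division.
- Crop/pad centres the grid with the odd voxel going to the high-index
  side, pads with 0, and translates the affine so retained voxels keep
  their world coordinates.
- On-disk format is NIfTI-1 (optionally gzipped); where qform and sform
  disagree, the sform wins. Voxel indices are 0-based.

Defaults (1.5 mm, clip percentiles 0.5/99.5, 256³ grid, 1 mm isotropic
for the segmentation path) suit whole-head T1-weighted scans. The
phantom studies in this package run at 24³/1.5 mm, chosen so the
phantom brain fills roughly half the field of view — see "Median
binarisation" below for why that matters.

## Classifiers

Three ReLU-only conv architectures share the head contract of global
average pooling followed by one fully connected layer to two class
scores: `tiny_3d` (three stride-2 conv blocks; the desk-scale default),
`residual_3d` (identity-skip blocks) and `dense_3d` (concatenative
blocks). Each conv is followed by batch normalisation (running
statistics at inference, so evaluation and attribution are
deterministic per sample); the substrate in `nativecam.nn` implements
forward and backward passes explicitly in float64 NumPy, which is what
lets the attribution code gate ReLU backward passes and read layer
gradients directly. Training uses cross-entropy, Adam at a fixed
learning rate of 10⁻³, batch size 2, validation every 2 epochs; the
best checkpoint maximises validation accuracy with ties to the earliest
epoch. Classification applies a strictly-greater 0.5 threshold on the
positive-class probability, so probability exactly 0.5 yields class 0.

ROC AUC is the trapezoidal area over probability thresholds
(equivalently the Mann-Whitney U statistic over n₁n₀; a test asserts
the identity to 1e-9). Groups containing one true class have no ROC
curve and are flagged rather than scored. Age stratification uses
half-open bins [5,10), [10,15), [15,20), [20,∞); under-5 records go to
a flagged cell.

## Attribution

Grad-CAM at a layer weights each activation channel by the spatial mean
of the class-score gradient, rectifies the weighted sum, and upsamples
trilinearly (centre-aligned grids) to the input resolution. Guided
backpropagation transmits a gradient through each ReLU only where the
forward input was positive and the incoming gradient is positive.
Guided Grad-CAM is their element-wise product, carrying the input
volume's affine bit-exactly. The raw product is the importance score
(no absolute value by default; an option exists).

Two conventions deserve explanation:

- **Layer choice.** The default attribution layer is the first
  convolutional block's *rectified* output (post-BN ReLU), the finest
  spatial resolution at which the network has nonlinear features.
  Grad-CAM's formulation weights activation maps, which are
  conventionally post-nonlinearity; on raw pre-normalisation conv
  outputs the maps were empirically not class-discriminative.
- **Class symmetry.** With a two-class softmax only the logit
  difference is identified; a training run may encode the same
  discriminative evidence as positive drive on either logit, and
  guided backpropagation — which follows positive-evidence paths only —
  sees that evidence from one class score but not the other. The
  pipeline's per-participant attention map is therefore the sum of the
  guided Grad-CAM maps for both class scores
  (`class_symmetric_guided_gradcam`), which is invariant to this
  arbitrary polarity. In validation studies roughly four in ten trained
  networks adopted the inverted polarity; single-class maps missed the
  planted effect on exactly those runs while the symmetric map found
  it. Per-class maps remain available (`gradcam`, `guided_backprop`,
  `guided_gradcam` with `target_class`), and the study pipeline can be
  switched to predicted-class or fixed-class attribution.

The study pipeline attributes the fully-trained final-epoch state. On
desk-scale cohorts validation accuracy saturates within a few epochs
while the features keep converging; attributing the earliest
best-accuracy checkpoint measurably degraded localisation. Checkpoint
selection for *prediction reporting* is unchanged (best accuracy,
earliest tie).

## Median binarisation and region scores

An attention map is binarised at its median q₅₀ (linear-interpolation
median; strictly greater → 1, ties → 0, so a constant map yields an
all-zero mask and an all-distinct even-count map flags exactly half its
voxels). Each region's relative frequency is the fraction of its voxels
flagged; counts are exact voxelwise tabulations, so the per-region
important counts partition the mask. Aggregation across participants is
the arithmetic mean of RFs (median available), with participants
lacking a region contributing 0. "Most predictive" regions strictly
exceed the 90th percentile of the RF column (background row included in
both the percentile and the candidacy, so an attribution leaking into
the background is visible rather than discarded); with n distinct RF
values and n a multiple of 10 this selects exactly n/10 regions.

Because the mask always flags half the volume, the RF contrast between
regions depends on where the median falls. If the brain occupies much
less than half the field of view the threshold sits inside the
background score distribution and every brain region is flagged at a
similar rate; with the brain near half the volume the median
discriminates within brain tissue. This motivates the 24³ crop used in
the phantom studies and is worth remembering when choosing crops for
real data.

## The phantom generator

The generator provides the statistical structure the pipeline assumes,
not anatomical realism: an ellipsoidal "brain" (semi-axes 0.4× the grid)
of base intensity 1 on zero background, partitioned into k irregular
parcels by nearest-seed (Voronoi) assignment from random interior
points, with hemispheres assigned by the seed's x-offset from the
midline. Class 1 adds `effect_size` inside the designated effect
parcels; Gaussian noise (sd `noise_sd`) is added inside the brain;
every participant's world coordinates are scaled by a factor drawn
uniformly from 1 ± `size_jitter`; the volume is then resampled to its
site's voxel spacing. Per-participant randomness is seeded by the
(cohort seed, participant index) pair, so cohorts are bit-reproducible
and participant order is immaterial. The test split is drawn entirely
from the last configured site (site-disjoint, 25% of each class by
default); the remaining participants rotate through the other sites
with 30% forming the validation set.

The head-size jitter is load-bearing. With a perfectly shared anatomy,
the planted effect shifts each volume's global mean and standard
deviation, so after per-volume z-scoring the (constant) background
level alone separates the classes and a classifier can succeed without
looking at the parcels. Size variability of ±4% (≈7% volumetric sd)
makes global intensity statistics uninformative about class — the
nuisance is of the same order as the effect's global footprint — while
leaving the local parcel contrast intact. Much larger jitter (±10%)
makes the 20-epoch training budget unreliable. A morphological effect
variant (parcel dilation rather than intensity) is out of scope of the
validation studies.

Default study conditions: 48³ grid at 1 mm, 30 parcels, effect parcels
(1, 2, 3), effect size 0.5, noise sd 0.2, 30 participants per class,
two sites with spacings (1.2, 1, 1) and (1, 1, 1) mm, ages uniform on
[6, 26) years, genders balanced.

**What passing tests show — and don't.** The phantom demonstrates that
the implementation recovers a localised, additive, class-pure intensity
effect through the full chain (heterogeneous grids → preprocessing →
training → attribution → affine transport → RF ranking). Real
structural MRI differs in every hard way: morphological rather than
intensity effects, anatomical covariance, scanner-specific intensity
distributions, partial-volume effects, label noise in diagnosis, and
effect sizes far below 2.5 per-voxel noise SDs. Success on the phantom
validates the machinery, not the claim that the method finds true
biology in any given cohort.

At the frozen conditions the end-to-end recovery study (validation
accuracy ≥ 0.9 and ≥ 2 of the 3 planted parcels in the top 3 of 30 by
mean true-positive RF) passed on 19 of 24 cohort seeds; the misses are
training runs whose perfectly-accurate classifier keyed on features the
first-layer attention does not localise to the planted parcels — an
honest failure mode of saliency methods on small networks, which the
aggregate-across-models tallies of the consistency analysis are
designed to absorb.

## Known limitations

- The NumPy conv-net substrate targets desk-scale grids (≤ 64³);
  training 256³ inputs is out of its performance envelope.
- Guided backpropagation's positive-evidence gating means single-class
  attention maps can miss evidence encoded with inverted polarity; the
  class-symmetric map mitigates but does not remove the dependence of
  saliency on the learned representation.
- The external segmentation network itself (and its trained weights) is
  deliberately out of scope; the package consumes its label volumes.
- Aggregation of RF across participants by mean (and the inclusion of
  the background row in percentile selection) are conventions chosen
  here; both are switchable, and group rankings under median
  aggregation are not claimed to be identical.
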