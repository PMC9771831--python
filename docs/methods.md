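# Methods

This note documents the models, algorithms and design decisions behind
`cerebseg`, in the order data flows through the pipeline.

## Label protocol

The cerebellum is represented by 27 disjoint structures: ten hemispheric
lobules per side (I–IV, V, VI, Crus I, Crus II, VIIb, VIIIa, VIIIb, IX, X),
five vermal segments (VI–X) and one white-matter label per side. Integer
ids are fixed and documented: 1–10 left lobules (superior→inferior), 11–20
right lobules, 21–25 vermis, 26/27 left/right white matter; 0 is
background. The left–right swap is an involution that fixes the midline
(vermis) ids. The table ships as a TSV lookup and a viewer color table.

**Cortex/white-matter merging.** When a gray-structure map and a separate
white-matter mask are combined, cortex labels win on overlapping voxels and
white matter fills only background (the gray source is treated as the
richer delineation; the precedence is configurable). Remaining gap voxels —
background voxels whose 26-neighborhood touches both tissue classes, or an
explicit gap mask — are assigned the gray id of their nearest gray voxel by
Euclidean distance in mm. Distance ties break toward the lowest label id,
which makes the operation deterministic; the implementation runs one exact
distance transform per present gray label, so ties are resolved exactly
rather than by the arbitrary choice an index-propagating transform makes.

## Phantom generator

The phantom emulates the geometry that matters for lobular segmentation,
not folial anatomy:

* two ellipsoidal hemispheres (default radii ≈ 0.19/0.23/0.17 of the grid
  extent) whose cortical shell is split into ten angular wedges per side —
  the "lobules" — by radial planes in the sagittal-plane angle;
* a midline vermis ellipsoid split into five wedges the same way;
* a white-matter interior per hemisphere plus randomly oriented branch
  tubes (default 6 per side, radius 1.6 mm) that reach into the cortical
  band, emulating white-matter strands;
* T1-like intensities (background 0.1, gray 0.5, white 0.8 on a [0, 1]
  scale), additive Gaussian noise with standard deviation 5% of the gray
  mean, and a smooth multiplicative intensity drift (peak ±10%) standing in
  for scanner inhomogeneity.

Subjects drawn with different seeds vary in center position (±1.5 mm),
per-axis radii (±4%), and wedge phase (±5°) — a modest, realistic level of
inter-subject anatomical variability. Atrophy `a ∈ [0, 1]` retracts the
outer cortical surface inward (shell thickness scales by `1 − a`) and
erodes the branch radius by the same factor, so gray and white matter
volumes both decrease monotonically. Retest pairs share one anatomy and
draw independent noise and drift. All randomness flows through
`numpy` generator streams keyed by `(seed, subject, purpose)`, so adding
new outputs never perturbs existing draws and everything is bit-reproducible.

Synthetic displacement fields (smoothed white-noise 3-vector fields,
boundary-tapered, rescaled to an exact peak magnitude) replace deformation
fields that would otherwise come from cross-subject registration of real
images; only the *application* of fields to images and labels is part of
the method proper.

**What the phantom does not emulate:** folia, true lobule shapes, partial
volume effects, MR acquisition physics, skull/CSF surroundings, or
pathology beyond global atrophy. Passing phantom experiments therefore
demonstrates the pipeline's mechanics (localization, slicing, learning,
aggregation, metrics) — not clinical segmentation accuracy on real MRI.

## Localization

The working crop is cubic with a fixed side (128 voxels by default).
"Symmetric placement" is implemented as extent-midpoint centering per axis
with floor rounding, clamped into the grid; grids smaller than the side are
zero-padded and the padding recorded, so crop→embed round-trips are exact.
Center-of-mass centering was rejected because midpoint centering gives a
containment guarantee for any mask narrower than the side.

## Augmentation

* **Affine (in-slice):** translation ±12 mm per in-plane axis, scaling
  0.95–1.2, rotation ±20°, all uniform; composed as translate·rotate·scale
  about the slice center; images resample linearly, labels nearest-neighbor,
  by backward warping. Identity parameters short-circuit to a bit-exact
  no-op.
* **Left–right flip:** applied volumetrically (a sagittal in-plane flip
  cannot realize a left–right mirror), mirroring both grids across the
  mid-sagittal plane and passing label ids through the lateral swap.
* **Bias field:** all 20 trivariate monomials `x^a y^b z^c`, `a+b+c ≤ 3`,
  in graded lexicographic order, on coordinates normalized to `[−1, 1]³`,
  coefficients uniform in ±0.5; the field is *added* to the [0, 1]-
  normalized intensities. Volumes are normalized at load (robust 0.1/99.9
  percentile min–max), then biased — this order makes the coefficient range
  meaningful and is configurable.
* **Non-linear deformation:** backward warping through a displacement
  field; a static augmented set pairs every field with a case such that
  each case is used at least once (round-robin over a permutation, then
  random assignment).

Label resampling is nearest-neighbor everywhere and can never invent ids.

## Reference network

The per-view model is a compact U-Net-style encoder–decoder written in
numpy: two resolution levels (configurable), 16 base filters, two 3×3
convolutions per block, each batch-normalized, with either a leaky-ReLU
or a local-competition activation (maximum over adjacent channel pairs,
a paired-channel maxout); 2×2 max pooling; nearest-neighbor unpooling with
additive skip connections; a 1×1 classifier head with softmax.
Convolutions are evaluated as im2col + BLAS matrix products in a
channels-last layout; every layer implements its analytical backward pass
(verified against finite differences in the test suite).

The network internally appends positional channels to its input — in-plane
coordinates on [−1, 1], the polar radius and angle about the slice center,
and the normalized slice position along the view axis (a CoordConv-style
encoding). Anatomy within a localized crop is strongly position-dependent,
and a shallow network cannot synthesize absolute position from padding
artifacts alone; the external contract (7-channel stacks in, class
probabilities out) is unchanged.

Checkpoints are `.npz` weight archives with a JSON config sidecar carrying
a hash of the label protocol; the pipeline refuses to aggregate checkpoints
trained under different protocols.

## Training

Defaults mirror the full-scale recipe: 70 epochs, batch 128, AdamW with
decoupled weight decay 1e-4 and initial learning rate 0.01, and
reduce-on-plateau scheduling — the learning rate is multiplied by 0.01
(read literally as ×0.01, not ×0.99; 0.1 would be the conventional value —
both are configurable) when validation macro Dice has not improved for 4
consecutive epochs; the bad-epoch counter resets on improvement and after
each reduction. The loss is class-weighted cross-entropy plus a soft-Dice
term (smoothing 1e-6); class weights are median-frequency
(`w_c = median(freq)/freq_c`, absent classes 0 with a warning); the
checkpoint with the best validation macro Dice is retained. Batches mix
slices across subjects within a view. Gradients are clipped at global norm
1. Runs are seed-deterministic.

Loss, class weighting and checkpoint selection are deliberate lineage
choices (they are standard for this family of segmentation networks) since
no single canonical choice exists; all are configurable.

## Multi-view machinery

Slice stacks clamp out-of-range neighbor indices to the nearest valid
slice (edge replication preserves boundary intensity statistics better
than zero padding). Per-view predictions are reassembled into the crop
volume and checked for per-voxel unit sum. The sagittal network trains on
17 lateral-merged classes (background, 10 lobule types, 5 vermis segments,
1 white matter); expansion to the full 28-class set copies each merged
probability to both lateral classes and renormalizes. View aggregation is
a weighted arithmetic mean with defaults (1, 1, 0.5) — the half weight
reflects the sagittal view's lateral ambiguity — followed by argmax with
ties broken toward the lowest class id.

## Evaluation suite

* **Dice** `2|G∩P|/(|G|+|P|)`; two empty masks score 1 (perfect agreement
  on absence).
* **Volume similarity** `1 − |V_G−V_P|/(V_G+V_P)` on volumes in mm³;
  grid-free; undefined (rejected) when both masks are empty.
* **Hausdorff distances** on boundary voxels (mask voxels with a
  6-connected non-mask neighbor; grid-face voxels count), voxel-center to
  voxel-center in mm. The pooled distance set is the **union** of the two
  directed minimum-distance sets — the standard symmetric construction
  (an intersection of the two directed sets would generically be empty).
  HD is the maximum; HD95 the nearest-rank 95th percentile of the pooled
  set, so HD95 ≤ HD always.
* **Per-structure reports** carry one row per structure plus merged
  regions (left/right cortical gray, vermis, left/right white matter) and
  a macro mean over structures present in both maps; missing structures
  carry NaN distances and are excluded from the macro mean with a count.
* **ICC** is two-way mixed, single measurement, consistency type:
  `(MS_subject − MS_error)/(MS_subject + MS_error)` for two scans, with a
  95% confidence interval from F-distribution bounds (formulas in the
  code); cross-checked against an independent statistical package in the
  tests. Exactly duplicated inputs return exactly 1.
* **Wilcoxon signed-rank** (two-sided): zeros dropped, exact null for
  n ≤ 25 pairs, normal approximation beyond; the reported statistic is the
  signed rank sum T⁺ − T⁻.
* **Outlier scan** flags values outside mean ± 2.5 SD per class.

## Desk-scale experiments

The experiments in `cerebseg.experiments` reproduce the pipeline's study
designs at sizes chosen to complete on one CPU within minutes; they are
the package's own problem sizes, and all are adjustable.

* **End-to-end training:** 40 training / 10 validation / 10 test phantoms
  on a 64³ grid spanning atrophy 0–0.4, a 48-voxel working crop (the same
  crop-to-volume proportion as 128-of-256), 2-level 16-filter networks,
  8 epochs of 1024 slices at batch 16, learning rate 5e-3, flipping as
  the on-the-fly augmentation. Accuracy target: aggregated macro Dice
  ≥ 0.80 on held-out phantoms, with aggregation at least matching the best
  single view. A measured run reaches ~0.87–0.88 aggregated macro Dice,
  with aggregation a few points above the best single view.
* **Ablation:** one view (axial) at 32³/24-crop in a deliberately
  data-starved regime — 4 training subjects, 2 validation, 8 test — with
  arms {baseline, flip, bias, affine, deformation (8 synthetic fields),
  full = all + pre-training on a 16-phantom low-noise pool}; every arm
  trains the same number of epochs (25) over its own dataset, repeated
  over 3 seeds and compared on test macro Dice. Arm augmentation
  magnitudes are matched to the cohort's actual variability (translation
  ±0.5 mm — localization centering cancels all but the box-rounding
  error — rotation ±5°, scaling ±4%, bias coefficients ±0.12); the printed
  full-scale ranges target real-MRI variation and overwhelm the miniature
  anatomy. The gentler plateau schedule (factor 0.1, patience 10) is used
  here: with tiny validation sets the printed factor 0.01 / patience 4
  collapses the learning rate on validation noise and freezes training.
* **Test–retest:** 20 phantom pairs (shared anatomy, independent noise and
  drift), segmented with the toy models; per-structure volume ICC across
  subjects.
* **Atrophy cohort:** 10 subjects at each atrophy level 0/0.2/0.4;
  segmentation-derived mean gray-matter volume per level.

The toy training uses a smaller batch and learning rate than the printed
full-scale defaults: at ~2000 training slices an epoch of 128-slice
batches would provide too few optimizer steps for convergence. Flip-only
augmentation is the accuracy-maximizing choice at this scale (the phantom
test distribution matches training); adding bias-field augmentation was
measured to change neither accuracy nor retest reliability materially.

**What the desk-scale experiments do and do not show.** The phantom
family's inter-subject variability is low-dimensional (seven jitter
parameters) and geometrically smooth, and the localization step cancels
positional variation. In this regime a converged baseline generalizes
well from very few subjects, so the measured benefit of individual
augmentations is small and not uniformly positive: left–right flipping
and static non-linear deformation tend to help (they add genuine
anatomical variety), while in-slice affine and bias-field augmentation
can cost more in label-interpolation noise and optimization burden than
their robustness buys on this data. Pre-training on a low-noise pool
transfers imperfectly to noisier targets at this scale. These are
properties of the miniature test bed, not of the method: on real MRI the
variability these augmentations address (scanner effects, centroid and
anatomy variation) is far larger than anything the phantom generator
emulates. The same caveat applies to test–retest reliability: with
between-subject volume spread of only a few percent (radii jitter ±4%),
volume ICCs of 0.92–0.99 are the expected outcome for models at ~0.87
Dice, and pushing every structure above 0.95 would require segmentation
accuracy beyond what minutes of CPU training produce.

## Numerical conventions and degenerate inputs

Argmax ties break toward the lowest class id. Probability fields are
float32 with unit-sum checks at 1e-5. The soft-Dice smoothing constant is
1e-6. Empty masks are rejected wherever a boundary or distance is needed;
the per-structure report records them as missing instead. The ICC guards
against floating-point cancellation in the error mean square (clamping at
zero) so duplicated inputs return exactly 1. Division-free paths are taken
for zero-amplitude fields and identity transforms, which are bit-exact
no-ops.

## Known limitations

* The phantom's wedge "lobules" have planar boundaries; real lobule
  boundaries follow folia and are far harder to delineate. Accuracy
  numbers on phantoms do not transfer to clinical MRI.
* The reference network is deliberately small; scaling `levels`,
  `base_filters` and `competition_enabled` up approaches a faithful
  architecture but has not been trained at full scale here.
* The localization step consumes an existing coarse label source; the
  whole-brain segmenter that produces it in production is out of scope.
* Rigid retest jitter is supported by the generator but the retest
  analysis compares volumes only (per-structure volumes are
  alignment-free), matching the intended use.
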