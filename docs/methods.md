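# Methods

`fetalvol` implements an automated measurement pipeline for fetal
intracranial volume (ICV) from 3D ultrasound-like volumes, together with the
synthetic data needed to exercise and validate every stage without access to
clinical data.  This note records the models, the parameters that matter,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Image model and measurement

A volume is a scalar 3D image with isotropic voxel spacing `s` (mm); a
segmentation is a strictly binary mask on the same grid.  The measurement is

    V = N · S,    S = s³ mm³,

the labelled-voxel count times the physical voxel volume, reported in mL
(÷1000).  Everything upstream of this equation exists to make `N` reliable:
reorientation so heads appear in a canonical pose, intensity normalization
to [0, 1], a segmentation network, ensembling, and a quality gate.
Intensities are interpolated trilinearly and masks are interpolated then
re-binarized at 0.5, so masks remain binary through every geometric
operation.  Constant-intensity volumes normalize to all zeros (degenerate
range; avoids 0/0).  Files whose per-axis spacings differ by more than 1%
are rejected rather than silently resampled.

## Phantoms

`make_phantom` renders an ellipsoidal head: a bright skull shell
(intensity 0.95) of configurable thickness, a mid-intensity interior
(0.45), darker banded background tissue (0.18 ± 0.06, bands move with the
anatomy so that pose is observable), optional acoustic-shadow cone below
the skull, and multiplicative speckle with clipped Gaussian amplitude
(clip at ±2.5 SD).  The ground-truth ICV mask is every voxel strictly
inside the shell's inner surface; the true ICV in mL follows by counting.
This is deliberately not an acoustic simulation — it provides exactly the
features the pipeline consumes (a bright closed boundary, textured
interior, orientation cues, nuisance background), no more.

`make_annotated_set` sizes heads so the two gestational waves keep the
reference mean-ICV ratio 250.9/81.3 ≈ 3.09, scaled so the larger head fills
about two-thirds of the field of view on whatever grid is requested; each
phantom gets ±8% volume jitter, rotations up to ±15° and small
translations.  At 32³ with 1 mm spacing the voxelized ratio runs a few
percent high (boundary voxels weigh more in the smaller head); it converges
to the analytic ellipsoid value as spacing shrinks, which is tested.

## Cohort simulator

The simulator draws a two-wave longitudinal cohort at the demographic
parameters of a large fetal ultrasound study (ages in days):

* wave-1 age: girls 155.7 ± 6.2, boys 154.4 ± 6.2 (clipped to [140, 171]);
* wave-2 age: girls 211.6 ± 5.7, boys 211.4 ± 5.8 (clipped to [199, 230]);
* interval 56.7 ± 7.8 days;
* age-adjusted sex effects +2.86 mL (wave 1) and +12.35 mL (wave 2) for boys;
* daily growth rates: girls 3.03 ± 0.39, boys 3.15 ± 0.40 mL/day;
* ~3 sweeps per wave (Poisson, minimum 1).

Sweep-level ICV at a wave is `wave_mean(age) + sex_effect·1[boy] + u_subject
+ ε_sweep` with `u ~ N(0, 8 mL)` and `ε ~ N(0, 4 mL)`.  The two variance
components are assumptions, not published values; 8/4 mL keep the standard
errors of the fitted sex effects near the published magnitudes at the
published sample sizes.  The wave mean curves are quadratics in age centred
at the wave mean age, anchored so the *marginal* per-sex means emerge from
the age-adjusted effects plus the small per-sex age gap: girls' wave-1 mean
ICV at 155.0 d is 79.75 mL with local slope 1.5 mL/day (so girls average
80.8 mL at 155.7 d and boys 81.7 mL at 154.4 d); girls' wave-2 mean at
211.5 d is 244.65 mL with slope 4.5 mL/day.  The marginal means and the
age-adjusted coefficients cannot both be generator primitives; the
age-adjusted coefficients are the primitives here.

`per_wave` and `longitudinal` modes are intentionally not forced to agree
with each other — they emulate a cross-sectional per-wave subsample and a
longitudinal best-scan subsample, which are different selections in real
cohorts.  QC scores are drawn so a configurable fraction (default 23%)
exceeds the 0.90 gate, independent of the ICV noise, so gating does not
bias the statistics.

## Preprocessing and registration

Raw volumes are aligned to a gestational-age template by a 12-DOF affine
registration; only the rigid part (orthogonal polar factor of the linear
part, translation kept) is applied, because scaling the anatomy would scale
the measurement.  Registration is implemented internally: translation
initialization from intensity centroids, then multi-resolution (downsample
factors 4, 2, 1) Powell maximization of normalized cross-correlation with
trilinear warping.  Transforms map reference physical coordinates into
moving coordinates; rotation is parameterized by Euler angles about the
reference-grid centre, affine adds log-scales and shears.  A registration
returning a non-finite objective raises; reflections (negative determinant)
are rejected in rigid extraction rather than silently rectified.

On noise-free ellipsoidal phantoms a 12-DOF fit can trade rotation against
shear (an ellipsoid maps onto a rotated copy of itself by a pure stretch),
so rigid-recovery accuracy is validated with the 6-DOF mode and with
warp-resample ground truth for the full affine; recovery tolerances
(translation < 1 mm, rotation < 2°) are contracts of this implementation
on phantoms, not claims about clinical data.

Cropping keeps the largest connected component of voxels above intensity
0.1 (after normalization) plus a margin, then resamples to 0.40 mm
isotropic by default (configurable; the synthetic experiments keep 1 mm).
Templates are voxel-wise mean volumes with majority-vote masks (ties
included).

## Augmentation

Each training pair is expanded with three augmented copies by default.  One
spatial transform (mirroring by exact slicing; rotation ±15°; scaling
[0.9, 1.1]; elastic displacement field with 16-voxel control spacing and
2-voxel SD, applied with probability 0.5) is sampled per copy and applied
identically to volume and mask; colour transforms (brightness ±0.1,
contrast [0.8, 1.25] about mid-grey, gamma [0.7, 1.5]) and noise transforms
(additive Gaussian SD up to 0.05, Gaussian blur up to 1 voxel) touch the
volume only.  Composition order is fixed (spatial → colour → noise);
outputs are clipped to [0, 1]; a measure-zero identity draw is redrawn so
every copy differs from its original.  The parameter ranges are declared
defaults, all overridable.

## Segmentation network

A 3D encoder-decoder CNN in NumPy: per encoder level one convolution
(kernel 5 at the first level, 3 elsewhere) + normalization + ReLU with
`f·2^level` filters and 2×2×2 max pooling; a bottleneck block with dropout
(rate 0.5); per decoder level nearest-neighbour upsampling, a 1³ projection
convolution, concatenation of the matching encoder feature map, and another
convolution block; a final 1³ convolution with per-voxel 2-class softmax.
Default depth is 3 encoder levels (configurable; the scaled-down
experiments use 2 at 32³).

Convolutions run as im2col matrix products in channels-last layout (the
window view's trailing axes then match the weight layout, so the gather
copy is cache-friendly); the input gradient of a same-padded odd-kernel
convolution is again one im2col product with the spatially flipped,
channel-transposed kernel.  Normalization statistics are computed per
sample over the spatial dimensions, identically at training and inference —
the stable choice when gradients accumulate volume by volume at an
effective batch size of one, and it makes prediction deterministic.  The
loss is sparse categorical cross-entropy, optimized with Adam; gradients
accumulate over the volumes of a mini-batch before each update, so memory
stays per-volume.  Exact softmax ties label a voxel background, the
conservative choice for volume estimates.

## Model selection

Subjects (all scans of a subject together) are partitioned into 3
subject-disjoint folds balanced by scan count.  The hyperparameter search
covers base filters f ∈ [8, 64], batch size ∈ [16, 64] and learning rate ∈
[1e-4, 1e-2] (log scale): each of 8 iterations proposes one configuration —
3 initial random draws, then the expected-improvement maximizer of a
Gaussian-process surrogate (Matern ν=2.5 + white noise, fitted to mean
validation Dice) over 256 random candidates — and trains it once per fold,
24 networks in all.  Training divergence is recorded on the entry, not
fatal.

Each fold's winner is the candidate with the highest mean validation Dice
(ties to the lower iteration index); two-sided Wilcoxon signed-rank tests
of its per-sample Dice against every other candidate are reported as
descriptive annotation — they do not gate the selection.  The three fold
winners form the ensemble: a voxel is intracranial iff at least 2 of 3
members label it so (no ties are possible with 3 members).

## Evaluation metrics

Voxel accuracy, Dice (both-empty pairs score 1.0, one-empty 0.0), and the
symmetric Hausdorff distance over the full labelled point sets, in voxel
units and mm (`hd_mm = hd_vox · s` on isotropic grids; for the solid masks
produced here the full-set symmetric HD equals the boundary-set HD).
Hausdorff on an empty mask raises rather than returning infinity, so empty
predictions cannot silently vanish into a mean.  Group comparisons between
gestational-age waves use the two-sided Wilcoxon rank-sum test, exact for
tie-free samples with both n ≤ 25, normal approximation with continuity
correction otherwise.  Boxplot-rule outlier screening covers every metric
except physical Hausdorff distance — across ages at a fixed voxel size the
voxel-unit contour distance is the comparable quantity.

## Quality control

The QC score of a predicted mask is its Dice overlap with the
gestational-age template mask mapped into the scan's native space through
the inverse of a fresh scan-to-template affine registration (the QC stage
re-registers rather than reusing the preprocessing transform, so it is
self-contained and also catches preprocessing failures).  Scans pass only
when the score strictly exceeds 0.90.  Registration failures score 0 with a
logged reason so heterogeneous batches complete.  The template for a scan
is chosen by nearest wave centre age (155 vs 211.5 days); a missing age is
an error.

## Statistics

Per wave, `icv ~ sex + age_c + age_c² + (1 | subject)` is fitted by maximum
likelihood (not REML, so the likelihood-ratio test of the sex effect
against the no-sex null is valid); age is centred at the wave mean, which
conditions the polynomial without touching the sex coefficient.
Longitudinal growth uses the best-QC scan per (subject, wave) — QC ties
break to the larger ICV, then first occurrence, making selection
order-invariant — and converts the ICV difference to mL/day by the exact
interval; subjects missing a wave, or with a non-positive interval, are
excluded (the latter with a warning).  Per-sex rates are compared with
Welch's t-test (zero variance in both groups with equal means returns
t = 0, p = 1 by convention).  A two-sample equal-proportion χ² test is
provided for demographic tables.

## Scaled-down problem sizes

The full-size configuration (128³ voxels at 0.40 mm, 50 epochs, the full
search box) is far beyond a laptop-minutes budget, so the package's
benchmark recipes run the identical code path at reduced scale, chosen once
as follows:

* **Segmentation benchmark**: 32³ phantoms at 1 mm, 90 training + 20
  held-out volumes, depth 2 with 3³ kernels, 3-fold CV, 2 search
  iterations, 10 epochs × 3 steps of batch 16 (~30 Adam updates per
  network).  With so few updates a learning rate below ~1e-3 cannot train,
  so the searched box is scaled alongside the data to f ∈ [8, 12], batch
  16, lr ∈ [1e-3, 1e-2].  The full default box remains available and is
  exercised by the toy bookkeeping run (8 iterations × 3 folds at 16³, one
  epoch).
* **Statistics**: cohorts of 1231 / 1380 / 849 subjects — the published
  per-wave and longitudinal sample sizes — run in seconds and are used
  as-is.

Passing these benchmarks shows the pipeline's machinery is correct and
self-consistent under the stated phantom and cohort models.  It does not
show clinical performance: the phantoms lack true speckle statistics,
maternal tissue, fetal pose extremes and annotation noise, and the
simulated cohort has exactly the generating structure the statistics
assume.

## Known limitations

* The NumPy network trains on CPU only and is sized for small volumes; at
  128³ with f = 64 it would be impractically slow.
* Registration assumes a single bright head-like object; it has no
  multi-modal similarity metric and no deformable refinement.
* The QC score depends on template quality; a biased template biases the
  gate.
* Hausdorff distances use full point sets; for non-solid masks a
  boundary-only variant would differ.
* The cohort simulator's variance components are assumptions; inference on
  real data should re-examine them.
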