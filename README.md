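# fetalvol

Automated measurement of fetal intracranial volume (ICV) from 3D
ultrasound-like volumes, and the longitudinal statistics to study sex
differences in prenatal brain growth.

Transabdominal 3D ultrasound makes it possible to follow fetal brain growth
at population scale, but each visit produces many sweeps of varying quality
and manually selecting and annotating the best scan does not scale.
`fetalvol` implements the full automated alternative as a Python library and
command-line tool:

1. **Preprocessing** — affine registration (12 DOF) of each volume to a
   gestational-age-specific template, application of only its rigid part
   (6 DOF), automatic cropping to the head, resampling to isotropic voxels.
2. **Augmentation** — spatial (elastic, rotation, scaling, mirroring),
   colour (brightness, contrast, gamma) and noise (Gaussian, blur)
   transforms expanding the training set three-fold.
3. **Segmentation** — a 3D encoder-decoder CNN (implemented in NumPy) with
   skip concatenation, trained with Adam on sparse categorical
   cross-entropy; hyperparameters (filters f ∈ [8, 64], batch ∈ [16, 64],
   learning rate ∈ [1e-4, 1e-2]) tuned by Bayesian optimization under
   3-fold subject-disjoint cross-validation; the three per-fold winners
   (selected by mean validation Dice, annotated with Wilcoxon signed-rank
   tests) combined by per-voxel **majority voting**.
4. **Measurement** — `V = N · S`: labelled-voxel count times voxel volume,
   in mL.
5. **Quality control** — Dice overlap between the predicted mask and the
   template ICV mask mapped into native space via the inverse affine;
   scans are kept only when the score strictly exceeds 0.90.
6. **Statistics** — per-wave linear mixed models
   `icv ~ sex + age + age² + (1 | subject)` fitted by maximum likelihood
   with likelihood-ratio tests of the sex effect, and per-sex daily growth
   rates `(ICV₃₀w − ICV₂₀w) / interval` from the best-QC scans, compared
   with Welch's t-test.

Because clinical cohort data are access-restricted, the package ships a
first-class synthetic module: ultrasound-like head phantoms (bright skull
shell, textured interior, speckle, acoustic shadow) with exact ground-truth
masks, and a two-wave cohort simulator whose age distributions, sex effects
(+2.86 mL at ~20 weeks, +12.35 mL at ~30 weeks) and growth rates
(girls 3.03 ± 0.39, boys 3.15 ± 0.40 mL/day) follow the published
demographics of a large fetal cohort.  Every stage is tested end to end on
these synthetic data.

## Worked example

Simulate a longitudinal cohort at the default demographic parameters and
re-estimate the growth-rate difference between boys and girls:

```python
from fetalvol.recipes import longitudinal_growth_recovery

r = longitudinal_growth_recovery(n_subjects=849, seed=1)
print(f"boys  {r['mean_rate_boys']:.3f} mL/day")
print(f"girls {r['mean_rate_girls']:.3f} mL/day")
print(f"difference {r['rate_difference']:.3f} mL/day "
      f"(Welch t = {r['welch_t']:.2f}, p = {r['welch_p']:.2g})")
```

```
boys  3.143 mL/day
girls 3.006 mL/day
difference 0.136 mL/day (Welch t = 4.80, p = 1.9e-06)
```

The generator's per-sex rate means are 3.15 and 3.03 mL/day; with 849
subjects the estimate lands within Monte-Carlo error of the generating
difference of 0.12 mL/day, and the sex difference is detected.

The segmentation pipeline at desk scale (90 training phantoms at 32³,
3-fold cross-validated search, majority-vote ensemble, 20 held-out
phantoms):

```python
from fetalvol.recipes import scaled_segmentation_benchmark

b = scaled_segmentation_benchmark(seed=1)
print(f"mean DSC {b.mean_dsc:.3f}, mean accuracy {b.mean_accuracy:.3f}, "
      f"mean HD {b.mean_hd_voxel:.2f} voxels")
```

```
mean DSC 0.964, mean accuracy 0.996, mean HD 1.26 voxels
```

Mean Dice above 0.93, voxel accuracy above 0.96 and Hausdorff distance
below 4.6 voxels mean the scaled-down ensemble segments held-out phantoms
with the quality band expected of the full-size pipeline.

The same stages are scriptable from the shell:

```bash
fetalvol simulate phantoms --n 6 --seed 0 --grid 32 --out data/
fetalvol simulate cohort   --n 200 --seed 0 --mode longitudinal --out cohort.csv
fetalvol train   --data data/ --folds 3 --iters 2 --seed 0 --out models/
fetalvol segment --model models/ --in data/phantom_000_20w_vol.nii.gz --out mask.nii.gz
fetalvol analyze --icv cohort.csv --out report/
fetalvol run-all --seed 0 --out pipeline_out/   # the whole chain, smoke scale
```

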