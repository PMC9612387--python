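# fetrad

Radiomic analysis of **visually FET-negative gliomas** from dynamic
[¹⁸F]FET PET.

About a quarter to a third of newly diagnosed gliomas show no visible
amino-acid tracer uptake above healthy background ("FET-negative"): either
*isometabolic* (uptake ≈ background, invisible in static images) or
*photopenic* (uptake below background). `fetrad` implements a complete,
testable pipeline asking whether quantitative image features can still
separate such tumors from healthy tissue:

1. **Parametric maps** from a 16-frame dynamic acquisition (7×10 s, 3×30 s,
   1×2 min, 3×5 min, 2×10 min): early `TBR_5–15` and standard `TBR_20–40`
   summation images normalized by the mean of a crescent-shaped contralateral
   background VOI, and a per-voxel time-to-peak (`TTP`) map in minutes p.i.
2. **Mirrored-VOI comparison**: the tumor VOI is reflected about the
   mid-sagittal plane (ventricle excluded) to give a shape-matched healthy
   reference region.
3. **93 radiomic features** per (image, VOI): 18 first-order + 75 texture
   features (GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5), IBSI-style
   definitions, implemented and oracle-tested in this package.
4. **Paired screening**: per-feature two-sided Wilcoxon signed-rank tests of
   tumor vs. mirrored background, with a significance census per image kind
   and cohort subgroup.
5. **Classification**: nested cross-validated (50 repeats × 5 stratified
   folds) balanced L2 logistic regression, multivariate per image kind /
   combined, and univariate per feature; performance as AUC mean ± sd over
   outer folds.

Because clinical dynamic PET data of this kind is not publicly available,
the package ships a **seeded synthetic phantom cohort** (default 46
patients: 29 isometabolic, 17 photopenic) whose time-activity curves realise
the two phenotypes: ascending kinetics peaking after 30 min p.i. with a late
level equal to background (isometabolic) or well below it (photopenic),
against an early-peaking healthy background. Every stage of the analysis is
exercised end-to-end on this cohort.

## Worked example

```python
from fetrad import (RunConfig, build_feature_table,
                    PairedFeatureScreen, TumorClassifier, ClassificationConfig)

cfg = RunConfig(n_patients=12, isometabolic_fraction=0.5, base_seed=7,
                noise_scale=0.05)
table = build_feature_table(cfg)          # 12 × 2 VOIs × 3 kinds = 72 rows

screen = PairedFeatureScreen(table, subgroups=("all",)).fit()
print(screen.summary())

cv = TumorClassifier(table, subgroups=("all",),
                     config=ClassificationConfig(n_repeats=5)).fit()
print(cv.summary())
```

prints

```
Paired Wilcoxon screen: significant features of 93 (p < 0.05)

image                        all
TBR_20_40               12 ( 13%)
TBR_5_15                14 ( 15%)
TTP                     14 ( 15%)

Nested-CV logistic regression AUC (5×5 stratified CV, balanced L2)

features                       all
TBR_20_40             0.74 ± 0.24
TBR_5_15              0.97 ± 0.14
TTP                   0.87 ± 0.22
All                   0.89 ± 0.21
```

Read: the TTP intensity features (mean, percentiles, energy, ...) sit at the
exact signed-rank floor for 12 pairs (p ≈ 0.0005) — every ascending tumor
voxel peaks at the end of the acquisition while background peaks early —
whereas TTP *texture* features carry little contrast here because at this
noise level both VOIs are nearly TTP-homogeneous. Early TBR classifies best
in this mixed cohort: ascending isometabolic tumors are dim at 5–15 min even
though they match background late, and photopenic tumors are dim in both
windows.

The same stages are available from the shell:

```bash
fetrad simulate --n 46 --photopenic-fraction 0.37 --seed 7 --out cohort/
fetrad maps --dynamic cohort/P001/dynamic.nii.gz \
            --schedule cohort/P001/schedule.json \
            --crescent cohort/P001/mask_crescent.nii.gz --out maps/
fetrad extract --image maps/TTP.nii.gz --mask cohort/P001/mask_tumor.nii.gz \
               --bins 32 --out features.csv
fetrad featuremap --image maps/TTP.nii.gz --mask cohort/P001/mask_tumor.nii.gz \
                  --feature glcm_Idmn --window 5 --out idmn.nii.gz
fetrad run-all --n 46 --seed 7 --out run/
```

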