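# Methods

## The analysis in one paragraph

Each (synthetic) patient contributes a 4D dynamic PET volume on a 16-frame
schedule (7×10 s, 3×30 s, 1×2 min, 3×5 min, 2×10 min; the durations sum to
2380 s, and the duration list is taken as authoritative — the late
quantification window is therefore [20 min, 39.67 min)). Three parametric
images are derived: duration-weighted summation images over the 5–15 and
20–40 min windows, each divided by the mean of a crescent-shaped
contralateral background VOI (TBR images), and a per-voxel time-to-peak map
(TTP, minutes p.i., at frame mid-times). From each parametric image, 93
radiomic features are extracted twice per patient — once over the tumor VOI
and once over the tumor VOI mirrored into the contralateral hemisphere with
ventricle voxels excluded. Features are screened with paired two-sided
Wilcoxon signed-rank tests (tumor − mirrored), and tumor-vs-background
discrimination is estimated with nested cross-validated balanced L2 logistic
regression, reported as AUC mean ± sd over outer folds.

## Synthetic cohort

The phantom stands in for clinical data that cannot be redistributed. It
emulates the *statistical structure* the analysis assumes, not scanner
physics.

**Geometry.** 64×64×48 grid of 3 mm isotropic voxels; ellipsoidal tumor
(radii jittered uniformly in 4–6 voxels per axis) strictly in one
hemisphere; midline ellipsoidal ventricle; crescent-shaped normalization
region (difference of two offset spheres) in the contralateral hemisphere,
kept disjoint from the mirrored tumor. Reflection is a pure index flip about
the mid-sagittal voxel plane — exact for the symmetric phantom, an
approximation for real anatomy (no registration is attempted).

**Kinetics.** Each tissue class follows a noiseless curve with two
controllable properties: the time of its maximum (`peak_time`) and its mean
over the late window as a ratio to background (`late_level`). Early-peaking
curves (background: peak at 4–6 min; ventricle: 2.5 min, late level 0.3) are
a gamma-variate rise/washout `(t/t_g)^α e^{α(1−t/t_g)}` (α = 3) plus a
saturating plateau `0.4·(1−e^{−t/3 min})`, with the gamma-peak location
solved by root-finding so the stationary point falls exactly at `peak_time`.
Ascending tumor curves are a bare slow gamma-variate (α = 1.2) peaking at
`peak_time` ∈ 33–39.6 min. Curves are scaled so the late-window mean equals
`late_level` × the background reference exactly (trapezoidal integration on
a 1 s grid). Isometabolic tumors draw `late_level` from N(1.0, 0.03) clipped
to ±8% — the operational meaning of "visually negative" is a late-window
contrast within 2% in the noise-free case; photopenic tumors draw from
N(0.65, 0.08) clipped to [0.40, 0.85]. A global per-patient amplitude in
U(0.8, 1.2) emulates injected-dose variation (TBR is invariant to it by
construction).

**Noise.** Zero-mean Gaussian per voxel and frame with
sd = `noise_scale`·√(level / frame duration in min), approximating the count
statistics of reconstructed frames (short early frames are noisier);
simulated activity is clipped at zero. Default `noise_scale` = 0.05, chosen
to give visually plausible frame images at the phantom's intensity scale
(late-frame background sd ≈ 1.6% of level, early bolus frames ≈ 15%).
Projection-domain Poisson simulation, attenuation, partial-volume and motion
effects are out of scope — so passing tests demonstrate the pipeline's
correctness and the phenotypes' separability under these idealized
conditions, not clinical performance.

**Determinism.** Per-patient seeds and parameter jitter derive from the
cohort base seed through `numpy` `SeedSequence` spawning; identical seeds
reproduce bit-identical volumes and byte-identical CSV outputs.

## Parametric images

* Window membership: a frame belongs to [t₀, t₁) if its mid-time does. With
  the default schedule, 5–15 min selects the frames with mid-times 7.17 and
  12.17 min and 20–40 min those at 24.67 and 34.67 min.
* Summation images are duration-weighted means rather than raw sums; the TBR
  ratio is identical either way for a fixed window, but means keep images
  comparable across windows.
* TTP is the mid-time of the first frame attaining the voxel's maximum
  (earliest-frame tie-break, no sub-frame interpolation). An optional odd
  moving-average smoothing window (shrinking at the edges) is available and
  off by default.

## Radiomic features

18 first-order + 75 texture features with IBSI-style definitions and
camel-case names comparable to common radiomics tools.

* **Discretization**: fixed bin count, default 32, spanning the in-mask
  [min, max]. TBR values are O(1) ratios and TTP takes at most 16 distinct
  values, so a fixed absolute bin width suited to SUV or CT scales would
  collapse the histogram. A fixed-bin-width mode
  (level = ⌊(x − min)/w⌋ + 1) is available.
* **First order**: population moments; kurtosis is not excess-corrected;
  entropy and uniformity use the discretized histogram; total energy scales
  energy by the voxel volume; percentiles use linear interpolation.
* **GLCM/GLRLM**: distance 1, the 13 unique 3D directions; matrices built
  per direction (GLCM symmetrized), features evaluated per direction and
  averaged; directions with no voxel pairs are skipped. Direction averaging
  makes all texture features exactly invariant to axis flips and axis-aligned
  90° rotations (property-tested).
* **GLSZM**: 26-connected zones; zone sizes partition the VOI voxel count
  (asserted in tests).
* **GLDM**: distance 1, α = 0 (equal gray level); the dependence size j
  counts the centre voxel plus its dependent neighbours, so j ∈ 1..27 —
  this matches the effective index that the common reference formulas divide
  by.
* **NGTDM**: neighborhood averages over in-mask 26-neighbours; voxels with
  no in-mask neighbour do not contribute. Coarseness of a perfectly
  homogeneous region is capped at 10⁶.
* **Degenerate conventions** (single gray level): skewness/kurtosis = 0,
  GLCM correlation and MCC = 1, entropies 0 — all flagged in the output
  rather than erroring, and carried into the feature table's `degenerate`
  column.
* **Local feature maps**: any of the 93 features evaluated on a sliding
  cubic window (default 5×5×5, clipped at borders) for visualization.

Correctness of all five matrix families is established against naive
scalar-loop constructions (20 random VOIs up to 8³, 1e-9 tolerance) plus
hand-enumerated toy cases; shape features are excluded by design (tumor and
mirrored VOIs share their shape exactly, so they carry no contrast).

## Feature screening

Paired two-sided Wilcoxon signed-rank on (tumor − mirrored) per feature.
Zero differences are dropped (classic convention; configurable analyses can
pre-filter instead). For n ≤ 25 usable pairs the p-value is exact: the
permutation distribution of the signed midrank sum over all 2ⁿ sign
assignments, computed by a shift DP over doubled ranks — correct in the
presence of tied |differences|, where textbook exact tables do not apply.
For larger n, a normal approximation with tie-corrected variance and a 0.5
continuity correction is used. The census counts features with p < 0.05
(strict) per image kind × subgroup, as count and as a percentage of 93
rounded to whole percent; no multiple-testing correction is applied to the
primary census, and a Benjamini–Hochberg-adjusted count is reported as a
clearly separated supplementary column.

## Classification

Balanced L2 logistic regression (liblinear). Pipeline per outer training
fold: standardize → drop zero-variance columns → tune C over a 7-point
logarithmic grid 10⁻³…10³ by stratified inner 5-fold CV on AUC (ties to the
smaller C) → refit → score the outer test fold with the decision function
(midrank tie handling via the standard AUC). Outer loop: 50 repeats × 5
stratified folds, each repeat a differently-seeded partition derived from
the master seed. The inner loop is a single stratified 5-fold: repeating the
inner loop 50 times as well would multiply cost ~50-fold without changing
which C wins on these sample sizes. Samples are VOIs, not patients
(`group_by_patient=True` gives the corrected grouped design). A
label-permutation option provides the null reference, and an intentionally
leaky selection routine (`leaky_best_feature_auc`) is kept solely as a
negative control for the leakage regression test.

## Problem sizes in tests and the acceptance script

Unit and property tests use a quarter-scale phantom (24×24×16) with the same
anatomy; the cohort-level acceptance checks use the full-size grid at the
prescribed cohort sizes (29 isometabolic / 17 photopenic). The acceptance
script reports multivariate AUCs at 10×5 outer repeats and the univariate
ranking at 3×5 with fixed C = 1 — the univariate report is a ranking of 279
single-feature models, where C-tuning changes essentially nothing and a
reduced outer loop keeps the whole script at desk scale; both sizes are
recorded in the output's `n` fields and in this note.

## Known limitations

* Mirror symmetry is exact in the phantom; real hemispheres are not
  symmetric, and the index-flip mirroring would need registration on real
  data.
* The TAC model is phenomenological — two degrees of freedom (peak time,
  late level), no compartmental interpretation, no input function.
* Gaussian noise approximates reconstructed-frame statistics; spatial noise
  correlation from reconstruction is absent, which tends to make texture
  contrasts cleaner than in clinical images.
* With low noise, noiseless ascending tumors give a *constant* TTP within
  the VOI; TTP texture over the tumor is then degenerate-by-convention
  (flagged). This is the idealized extreme of the "higher TTP homogeneity in
  tumor" phenotype.
* The samples-are-VOIs CV design ignores the tumor/mirrored pairing; the
  grouped design is provided but off by default to match the primary
  analysis.
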