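# Methods

## Problem and setting

Roughly a quarter of patients with locally advanced esophageal cancer do
not respond to neoadjuvant chemoradiotherapy (nCRT). Identifying likely
non-responders *before* treatment — from the baseline FDG-PET scan and a
handful of clinical covariates — would let clinicians consider alternative
strategies early. `petresponse` implements the full analysis chain for this
prediction problem: radiomic feature extraction from SUV-calibrated PET
volumes, feature normalization, a four-stage feature-selection cascade, an
exhaustive cross-validated sweep over 144 selection-strategy x classifier
pipelines ranked by average precision, and a top-10 soft-voting ensemble.

The clinical cohort this design targets (about 199 patients, ~29%
non-responders, labeled by Mandard tumor-regression grade 4–5 or interval
progression) is not publicly available. The package therefore ships
first-class synthetic generators so that every stage is exercised,
validated and benchmarked end to end without any download.

## Imaging chain

**Volumes.** `SUVImage` / `VOIMask` wrap 3-D grids with voxel spacing and
origin in mm; NIfTI I/O goes through nibabel, with spacing taken from the
affine. SUV values must be finite and non-negative.

**Delineation.** `delineate_suv_threshold` keeps the largest 26-connected
component of voxels strictly above an absolute SUV or a percent-of-maximum
threshold inside an optional seed region. The default is 40% of maximum — a
common PET choice — and is configurable rather than hard-coded, because
thresholds in clinical delineation tools vary; clinically corrected masks
can instead be supplied as external NIfTI files.

**Resampling.** Image and mask are trilinearly interpolated
(`scipy.ndimage.map_coordinates`, order 1) onto a 2 mm isotropic grid
sharing the input origin and kept inside the input extent. The interpolated
mask is rounded to binary with **0.5 rounding up**: an inclusive boundary
avoids dropping one-voxel-thin structures. Constant volumes are preserved
exactly and linear ramps reproduce exactly on interior voxels — both are
tested properties.

## Radiomic features

**Discretization.** SUV is binned with a fixed bin width of 0.25 SUV
anchored at zero: `bin = floor(SUV / 0.25) + 1`. Anchoring at SUV 0 (rather
than at the VOI minimum) makes bins comparable across patients. A value
exactly on a bin edge lands in the upper bin; discretization is monotone.

**Merged texture matrices.** Gray-level spatial structure is scored in 3-D
with 26-voxel connectivity into a *single merged matrix* per family rather
than averaging per-direction features:

- **GLCM** — co-occurrences over all 13 unique direction pairs at Chebyshev
  distance 1, counted in both orderings, summed into one symmetric matrix
  and normalized to sum 1.
- **GLRLM** — maximal equal-level runs from the 13 directions pooled into
  one (level x length) count matrix. For the merged matrix, run percentage
  is normalized by 13 x the voxel count (each voxel can start or extend a
  run in every direction).
- **GLSZM** — 26-connected equal-level zones (direction-free).
- **NGTDM** — per level, the count of voxels with at least one in-VOI
  neighbor and the summed absolute difference between the voxel level and
  the mean level of its in-VOI 26-neighborhood.

Merging makes every derived feature exactly invariant to axis permutation
on isotropic grids; the builders are verified against brute-force
pair-counting / line-walking / flood-fill oracles on exhaustive small random
grids.

**Registry.** The default panel names exactly 143 features across the
standard IBSI families: morphology 18, local intensity peaks 2, total
lesion glycolysis 1, first-order SUV statistics 22, intensity histogram 25,
intensity-volume histogram 12, GLCM 26, GLRLM 16, GLSZM 16, NGTDM 5. The
composition is an editable JSON manifest; the packaged default simply pins
this panel. Five features form the *conventional* PET subset used
downstream: metabolic volume, SUVmax, SUVpeak, SUVmean, TLG.

Numerical conventions worth noting:

- surface area uses deterministic voxel-face counting (slightly
  overestimates smooth surfaces; sphericity of a digital ball therefore
  converges from below as spacing shrinks);
- SUVpeak is the mean over a 1 cm³ sphere; `intensity_peak_global` places
  the sphere to maximize that mean over VOI centers, `intensity_peak_local`
  centers it on the hottest voxel. VOIs smaller than the sphere fall back
  to SUVmean with a warning;
- zero denominators in degenerate cases (constant VOIs) return 0 with a
  warning instead of raising, so flat phantoms pass the whole registry;
  GLCM correlation returns 1 for a zero-variance matrix.

## Feature normalization

Continuous features are normalized with constants estimated on training
rows only, branching on the Fisher–Pearson moment skewness
g1 = m3 / m2^{3/2}:

- |g1| <= 0.5 (boundary inclusive): robust scaling — subtract the training
  median, divide by the training IQR (zero IQR falls back to unit scale
  with a warning);
- |g1| > 0.5: Yeo-Johnson power transform with the maximum-likelihood
  lambda (scipy), followed by standardization to training mean 0 / SD 1 so
  that both branches land on comparable scales for PCA and penalized
  models.

The boundary case is assigned to the robust branch because "approximately
symmetric" is naturally read as inclusive. The fitted plan (branch, median,
IQR, lambda, mean, SD per feature) serializes to JSON for audit and is the
only thing ever applied to test rows.

Clinical covariates are encoded once — histology as a binary
adenocarcinoma indicator, clinical T-stage (T4a coded 4) and N-stage as
integer ordinals — and pass through normalization untouched; their 0–4
range is already commensurate with robustly scaled features.

## Feature-selection cascade and strategy grid

1. **ICC preselection** — radiomic features with multi-vendor
   reproducibility ICC < 0.6 are dropped (strict inequality; 0.6 itself is
   kept). True published per-feature ICC values are not redistributable, so
   the packaged manifest (`icc_manifest_synthetic.csv`) is a synthetic
   stand-in that flags 22 of the 143 default features, reproducing the
   143 → 121 arithmetic of the reference analysis; users supply their own
   manifest for real data.
2. **Redundancy pruning** — after normalization, any non-conventional
   feature with |Pearson r| > 0.8 against a conventional feature is
   removed; conventional features always stay. Zero-variance features have
   undefined correlation and are retained with a warning.
3. **Optional PCA** — the minimal leading set of components whose
   cumulative explained variance is strictly above 95%, fitted on training
   rows; clinical columns participate (the reference analysis selected
   principal components of "clinical and radiomic features").
4. **One of six univariable filters** — logistic |Wald z| (vectorized
   Newton–Raphson per feature; perfect separation scores infinity), ANOVA
   F, Fisher score, ReliefF (k = 5 nearest hits/misses, range-normalized),
   Welch |t|, and best single-threshold Gini impurity decrease. Scores sort
   descending; all ties break lexicographically by feature name for
   platform-stable determinism. The filter cut `k` is a tuned
   hyperparameter (default grid {2, 5, all}).
5. **Optional LASSO** — support of an L1-penalized logistic fit
   (liblinear) at penalty lambda, tuned in cross-validation (default grid
   {0.25, 1.0}); an empty support falls back to the single best-ranked
   feature with a warning.

{PCA on/off} x {6 filters} x {LASSO on/off} gives the 24 selection
strategies; crossed with 6 classifiers this is the 144-pipeline grid.

## Model selection and evaluation

The cohort is split 70/30 by proportional per-class rounding (199 patients
with 57 positives give exactly 139 train / 60 test with 40 / 17
positives). On the training subset each pipeline is scored by **average
precision** (AP, the step-summed area under the precision–recall curve)
over a stratified 2-fold cross-validation repeated 5 times — 10 validation
scores per pipeline. AP is the right selection metric for a 29%-prevalence
problem: it ignores true negatives, and a chance classifier's expected AP
equals the prevalence, so any excess over the test-set prevalence is
signal. (At small n the expectation of a random ranking sits slightly
above prevalence — about 0.33 for 17/60 — a finite-sample effect the test
suite documents.)

Every data-dependent stage (normalization, redundancy pruning, PCA, filter
ranking, LASSO, classifier) is re-estimated inside each fold on that
fold's training half. Because those stages do not depend on the classifier
or on `k`, the trainer fits them once per fold and shares them across the
grid — mathematically identical to refitting per pipeline and roughly two
orders of magnitude faster. During CV, SVMs are scored by their raw
decision values: AP is rank-based and Platt calibration is monotone, so
the AP is identical and the internal calibration CV is skipped; final
refits use calibrated probabilities.

Classifiers and default tuning grids (chosen small to keep the full
144-pipeline sweep on a single CPU at a few minutes; the grid *structure*,
not these values, is the design point): logistic regression C in {0.01,
0.1, 1, 10}; SVM C in {0.1, 1, 10} x {RBF, linear}; random forest 50 trees
x depth {3, unlimited}; Gaussian naive Bayes; one-hidden-layer MLP (16
units, lbfgs); K-nearest neighbors k in {3, 5, 11}. No resampling or class
weighting is applied; AP-based selection is the imbalance handling.

The leaderboard keeps one row per (strategy, classifier) cell with its
best hyperparameters by mean CV AP, sorted descending, ties broken by
pipeline name. The ten best pipelines are refitted on the full training
subset and combined by **soft voting** (arithmetic mean of positive-class
probabilities). The best single model and the ensemble are evaluated once
on the held-out 30% — AP, ROC AUC, PR and ROC curves, and the chance
baseline (test prevalence). A learning curve refits the selected pipeline
on stratified subsamples of each CV fold's training half; at the full fold
size it reproduces the cross-validated AP exactly.

Subgroup analyses restrict the cohort *before* the split: `t3plus` keeps
clinical T3–T4a tumors, `adeno` keeps adenocarcinomas.

## Synthetic data: what it emulates and what it does not

`generate_cohort` emulates the study conditions: ~199 patients at ~29%
non-responder prevalence (labels allocated by count-then-shuffle so the
count is exact for every seed), ellipsoidal tumors of 8–22 mm radius at
the native PET voxel size (3.1819 x 3.1819 x 2 mm), base uptake 4–12 SUV,
and clinical covariates drawn from realistic marginal proportions of such
a cohort (≈89% adenocarcinoma, mostly T3, node-positive) independent of
the label. Intratumoral texture is a Gaussian random field (kernel-smoothed
white noise, ~4 mm correlation length, amplitude 10% of base SUV) — the
simplest controllable heterogeneity that GLCM-family features detect. The
`heterogeneity_effect` parameter inflates the field amplitude and
correlation length in non-responders, planting an association between
texture heterogeneity and the label; at effect 0 the image distribution is
identical in both classes.

`generate_feature_table` skips imaging: standard-normal features drawn in
correlated blocks (mirroring the heavy redundancy of real radiomic panels,
where most features correlate strongly with at least one other) with an
optional mean shift of `effect_sd` standard deviations on a few planted
features in the positive class.

Not emulated: scanner physics, reconstruction protocols, attenuation,
partial-volume effects, delineation ambiguity, or any claim about the
actual imaging phenotype of non-responders — the planted effect is a
sensitivity instrument, not biology. Consequently, passing tests show that
the pipeline recovers signal when it exists and reports chance when it
does not; they say nothing about how much signal real baseline PET
carries. The reference clinical result (test AP ≈ 0.66 against a 0.28
baseline) is not reproducible here because the patient data are not
deposited.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full 24 x 6 grid once on a 199-patient
planted-signal tabular cohort (50 features, 5 planted at 2 SD), and a
reduced grid (2 strategies x 2 classifiers) on ten 199-patient null
cohorts; the test suite uses the same reduced grid for its 20-cohort
chance-level check. Texture oracles run on exhaustive random grids up to
6³; ranking-metric oracles on every binary label vector of length ≤ 8.
These sizes are the package's default desk-scale settings.

## Known limitations

- The 143-name registry composition and the ICC manifest are package
  choices standing in for study-specific lists that are not public.
- Filter hyperparameter grids are deliberately small; users with more
  compute can widen `HyperGrids`.
- Tuning and model selection share the same 2 x 5 CV (no nesting), so the
  leaderboard's CV AP of the winning cell is an optimistic estimate; the
  held-out test subset is the honest number.
- No probability calibration study, bootstrap/DeLong confidence intervals,
  or decision-curve analysis.
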