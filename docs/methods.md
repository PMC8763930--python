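# Methods

This note records the models behind `thyropet`, the defaults that matter,
and the numerical choices a maintainer would otherwise have to reverse
engineer. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A cytologically indeterminate (Bethesda III/IV), FDG-avid thyroid nodule
has roughly a 25–30% prior probability of malignancy. The pipeline
estimates that risk per patient from a PET image and two clinical flags,
producing (i) a continuous radiomics score (RS), (ii) a dichotomised RS,
and (iii) a 0/1/2 combined score counting positive biomarkers among
{RS-positive, Bethesda IV}.

## Segmentation

The lesion is the 26-connected component of `{voxel : SUV > T}` containing
a physician-chosen seed, with `T` the arithmetic mean SUV of a
contralateral-lobe region supplied by the user (the package never tries to
find that region automatically). Choices:

* **Strict inequality.** Voxels exactly at the threshold count as normal
  tissue. On constant regions the mean is returned exactly (no summation
  round-off), so noiseless phantoms segment bit-reproducibly.
* **26-connectivity**, the standard for hot-spot growing; a component that
  touches the grid boundary is flagged (`touches_boundary`), not rejected.
* **Volume exclusion.** Lesions with `volume < 3.0 mL` are excluded;
  exactly 3.0 mL is kept (the rule is "< 3 mL").

Degenerate inputs: an empty contralateral region and a sub-threshold seed
are errors (the seed error names the offending SUV and threshold).

## PET metrics and radiomics features

`SUVmax`/`SUVmean` are max/mean over the mask, `MTV` the mask volume in
mL, and `TLG = SUVmean × MTV` stored as the exact product (the identity
`TLG / SUVmean == MTV` is a test, not a rounding accident).

Preprocessing defaults: trilinear resampling to 2 mm isotropic voxels
(nearest-neighbour for the mask) and fixed-bin-width discretization at
0.25 SUV, `level = floor((x − min)/width) + 1`. Both are exposed in
`PreprocessSpec`; they are common PET-radiomics practice, and no
downstream acceptance check depends on the exact values. A
fixed-bin-count mode is available.

**Shape (14 features).** Surface area and volume come from a triangulated
mesh. Marching cubes straight on a binary mask inflates the area of
curved surfaces by staircase faceting (~9% for digital spheres, pushing
sphericity to ~0.91); voxel-face counting is worse (~50% inflation).
We therefore mesh the **zero level set of the signed Euclidean distance
field smoothed with a Gaussian of σ = 0.65 voxels**. Smoothing a linear
ramp does not move its zero crossing, so planar faces stay exact while
the staircase on curved surfaces relaxes; edge rounding is confined to a
sub-voxel scale. With this estimator a radius-10 digital sphere scores
sphericity ≈ 0.99 and a large digital cube approaches the closed form
(36π)^{1/3}/6 ≈ 0.806 (both computed in the tests). Axis lengths use
4·√λ of the voxel-coordinate covariance eigenvalues; maximum 2D/3D
diameters use convex-hull vertex pairs of the mesh. A single-voxel mask
returns the analytic values of one voxel cuboid instead of NaNs.

**First order (18 features).** Population moments on raw SUVs; kurtosis
is the non-excess (Pearson) form. Entropy and uniformity use the
discretized levels, log base 2.

**GLCM (24 features).** For each of the 13 unique 3D offsets at distance
1 voxel, a symmetric co-occurrence matrix over in-mask pairs is
normalised to probabilities; features are computed per direction and
averaged (directions without a valid pair are skipped). **Grey levels
are 1-based**, which matters for magnitude-bearing features:
`Autocorrelation = Σᵢⱼ p(i,j)·i·j` equals exactly 1 for a constant
lesion and 2 for a strictly alternating two-level stripe read along the
stripe axis. Degenerate conventions: correlation of a constant region
is 1; MCC of a single-level matrix is 1.

## Synthetic data

### Phantoms

A phantom is two ellipsoidal "lobes" in a 64³ grid of 2 mm voxels over a
0.05-SUV floor, one lobe harbouring the lesion, the other clean for
threshold estimation. Defaults: background 1.2 SUV, lesion mean 5.0 SUV,
Gaussian noise SD 0.08 SUV.

* **Shape.** The lesion boundary is `r(u) = r₀(1 + a·g(u))` with `g` a
  smooth random function on the sphere (six random low-frequency cosine
  waves, unit RMS) and `a = 0.45 × shape_irregularity`; `r₀` is
  calibrated by bisection on the rasterised volume, so the truth-mask
  volume hits the target within a voxel layer. One dial, provably
  monotone in extracted sphericity (tested as rank ρ < −0.9 over 10
  levels).
* **Texture.** A Gaussian random field smoothed with
  σ ∈ [0.3, 3.0] voxels mapped from `texture_coarseness`, then
  **rank-transformed to fixed Gaussian quantiles** (SD = 18% of the
  lesion–background contrast). The copula construction means coarseness
  changes only the spatial arrangement, never the marginal distribution —
  otherwise the sample minimum, which anchors grey-level binning, would
  leak correlation length into first-order statistics and invert the
  intended GLCM-autocorrelation ordering.
* **Peri-nodular background.** The ipsilateral lobe is set to 0.85 × the
  contralateral background. With symmetric noise centred exactly on the
  threshold, half of the background exceeds it and 26-connected region
  growing floods the lobe (site-percolation threshold ≈ 0.10); the
  0.85 factor keeps the threshold ~2 noise-SDs above the local
  background, which is the regime in which the clinical fixed-threshold
  protocol is well-posed. It also matches the mildly suppressed uptake
  of compressed peri-nodular parenchyma.
* **Two-centre effect.** Centre B multiplies all SUVs by 1.12 and
  inflates noise by 1.2, giving the per-centre Z-score step something
  real to remove. No published per-centre distributions exist, so the
  magnitude is a simulation choice.

Not modelled: scanner physics (PSF, TOF, attenuation), respiratory
motion, DICOM. Passing phantom tests therefore demonstrates correctness
of the pipeline's mathematics, not robustness to reconstruction
artefacts.

### Cohorts

`generate_cohort` emulates a 78-patient cohort: exactly
`round(0.295 × n) = 23` malignant rows by stratified draw; Bethesda IV
drawn conditionally on histology (P(IV|malignant) = 18/23,
P(IV|benign) = 25/55, recalibrated to the 43/78 marginal); TSH lognormal
matched to median 1.7 and IQR 1.1–2.3 mIU/L and independent of outcome;
log-normal SUVmax/MTV anchors; six redundant features Gaussian-copula
rank-correlated at ρ = 0.9 with the anchors; forty independent noise
features. The two informative features are class-conditional Gaussians
with a 0.8-SD downward shift in malignant lesions — equal-covariance
conditional Gaussians make the malignancy posterior exactly logistic in
the two features, which is the model the LASSO stage assumes and what
makes parameter-recovery tests meaningful. Signs match the reference
signature: lower sphericity and lower autocorrelation are malignant-like.

## Signature construction

Stage order is fixed: Z-score → redundancy filter → LASSO → RS → cut-off.

* **Z-scores** use the sample (n−1) SD, per acquiring centre by default
  (the motivation for Z-scoring is the two-scanner acquisition); pooled
  mode is a flag. Zero-variance features are an error naming the feature;
  the pipeline orchestrator drops within-stratum-constant columns first.
* **Redundancy filter:** remove a feature iff |Spearman ρ| > 0.7 against
  SUVmax or MTV *and* the Benjamini–Hochberg-adjusted p (one family over
  all feature × anchor tests, t-approximation p-values) is < 0.05.
  Anchors are exempt; TLG is treated as an ordinary candidate (it is
  near-deterministically correlated with MTV, so in practice the filter
  removes it; callers who want the exact published candidate set can drop
  it beforehand, as the pipeline does).
* **LASSO:** scikit-learn L1 logistic path over 30 penalties
  (C ∈ 10^[−2.5, 1.5]), penalty chosen by seeded, outcome-stratified
  ten-fold CV minimising the binomial deviance ("lambda-min"; a
  published selection of 2 features from 44 candidates is lambda-min-like
  behaviour). The "1-SE" rule is an option. Fold count degrades
  gracefully to the minority-class size. If nothing survives, the error
  suggests the fallback rather than silently refitting.
* **RS** is the coefficient-weighted sum of the standardized selected
  features, no intercept — linear by construction.
* **Youden cut-off:** candidate thresholds are midpoints of adjacent
  distinct scores; maximise J = sens + spec − 1, ties broken toward
  higher specificity (rule-in emphasis). AUC uses the midrank
  (Mann–Whitney) formulation; constant scores give exactly 0.5.
  **Orientation** is determined automatically: the positive side is the
  one whose oriented AUC exceeds 0.5. With negative coefficients on
  z-scored features, malignant-like (lower) feature values produce a
  *higher* RS, so for the reference signature "RS-positive" is RS above
  the cut-off — consistent with "increased RS" being the reported risk
  factor.

## Risk model

* 2×2 performance: sens = a/(a+c), spec = d/(b+d), acc = (a+d)/n,
  PPV = a/(a+b), NPV = d/(c+d) (percent); OR = ad/bc with Wald 95% CI
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`. The Haldane–Anscombe +0.5
  correction fires **only** when a cell is zero and is flagged — on
  all-positive tables the plain cross-product must reproduce printed
  reference CIs exactly.
* Combined score = rs_positive + bethesda_iv ∈ {0,1,2}; per-group
  prevalence, OR vs score 0, NPV(score 0), PPV(score 2), and a
  Cochran–Armitage trend test with scores fixed at (0,1,2) (the score is
  ordinal by construction).
* Logistic regression is plain ML (statsmodels), Wald CIs; "stepwise"
  multivariate analysis is backward elimination at p < 0.05 from the full
  two-predictor model (with two predictors this equals the full model
  whenever both are retained). Complete separation raises with a pointer
  to penalised alternatives rather than returning divergent estimates.
* Association tests: Pearson chi-square without Yates correction by
  default (a flag enables it), two-sided Fisher exact, tie-corrected
  Mann–Whitney U.
* **Bootstrap optimism (Harrell):** B resamples with replacement; per
  resample the model is refit, optimism = mean(AUC on resample − AUC of
  that fit on the original data), corrected = apparent − optimism.
  Resamples missing a class are redrawn and counted. B = 1000 default;
  tests and the acceptance script use B = 200, which bounds the Monte
  Carlo SE of the correction well below the tolerances checked.

## Problem sizes used in tests and the acceptance script

Simulated checks run at the study scale (n = 78, 23 malignant, 10-fold
CV): 100 seeded cohorts for recovery rates, 200 (tests) / 100 (script)
replicates for null AUC calibration, 10 (tests) / 20 (script) datasets ×
B = 200 for null optimism correction, 10 irregularity levels × 3 seeds for the
sphericity monotonicity check, and 64³–86³ voxel grids for phantom
geometry. These sizes keep each Monte Carlo standard error several times
smaller than the corresponding acceptance band.

* **Residual optimism.** On effect-free data (two fitted noise predictors,
  n = 78) the corrected AUC averages slightly above chance (~0.53–0.54
  across replicate datasets, computed in the acceptance script): Harrell's
  bootstrap under-corrects a little in small samples when the apparent AUC
  is itself inflated. This is a property of the estimator, not of the
  implementation, and stays within the ±0.05 calibration band we check.

## Known limitations

* The published cohort-specific quantities (AUC 0.733/0.730/0.818/0.728,
  coefficients −0.157/−0.285, cut-off 0.049, multivariate ORs 9.5/6.5)
  depend on the unavailable patient images; they are carried as reference
  constants (`REFERENCE_SIGNATURE`) and checked only structurally (signs,
  ordering, linear arithmetic).
* The contralateral-lobe region is a required input; its delineation is
  outside scope.
* GLRLM/GLSZM/NGTDM/GLDM families (51 of 107 published features) are not
  implemented: the selected signature uses none of them.
* No bit-parity with any external feature-extraction package is claimed;
  feature definitions follow the IBSI conventions stated above.
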