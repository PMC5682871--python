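# Methods

## Problem and data model

The package compares in-vivo CMR measures of myocardial infarction with
histological fibrosis at the level of histology sections.  One short-axis
LV slice per animal is analysed.  All spatial quantities live on a polar
data model around a fixed LV center: contours are radius functions of
angle, and every CMR export is a `SectorProfile` — one value per equal
angular sector (48 sectors for strain, 60 for wall thickening, 360 for
transmurality and signal intensity, matching the export conventions of the
clinical tools the measures come from).

**Angular convention (repo-wide).** Degrees, counterclockwise in the
(x, y) image basis, measured at the LV center and normalized to [0, 360).
After registration, 0° sits at the mid-lateral landmark.  Sector *k* of
*K* covers the half-open span [k·360/K, (k+1)·360/K); boundary angles
belong to the higher sector.  One fixed convention shared by every module
removes off-by-one sector bugs.

## CMR quantification

**Wall thickening.** WT(θ) = epi(θ) − endo(θ) along rays from the fixed
center ("ray" rather than chord distance — the exported quantity's exact
definition in the source tools is not recoverable, and ray distance is the
natural choice on the polar model).  The end-systolic frame is the frame
of minimal endocardial cavity area (computed as ½∮r²dθ) unless an explicit
index is supplied; end-systole is otherwise undefined for contour series.

**Strain.** Strain is computed geometrically from the contours, not by
gray-value feature tracking: commercial FT algorithms are closed, whereas
the geometric definition reproduces the meaning of the exported
quantities and is exactly testable.  With end-diastole as Lagrangian
reference, per sector: ε_cc = 100·(L_es − L_ed)/L_ed with L the midwall
arc length (midwall radius = (endo + epi)/2; on a uniform angle grid the
sector arc length is proportional to the sector-mean midwall radius), and
ε_rr = 100·(T_es − T_ed)/T_ed with T the sector-mean wall thickness.
Shortening is negative, thickening positive.  This is a methodological
substitute for image-based feature tracking and is labelled as such.

**LGE delineation.** FWHM thresholds at half the maximal intensity within
the seed region (default: the whole myocardium, overridable) and includes
pixels *at* the threshold (≥); the SD-from-remote family thresholds at
mean + n·SD of a remote region and is strict (>), following the usual
"higher than" phrasing.  The SD is the population SD (divisor N); the
convention is not fixed by any source and is switchable in one place.
Manual correction subtracts an exclusion region and suffixes the method
tag with "m".  No connectivity or feature-size filtering is applied.
%TM is area-based per 1° wedge: scar pixels / myocardial pixels, in
percent; wedges without myocardial pixels are flagged missing (NaN), which
happens when the wedge arc is finer than the pixel grid.

## Histology quantification

Tissue classification is a fixed hue/saturation partition in HSV space:
blue-dominant → connective tissue, red-dominant → cardiomyocyte,
green-dominant or low-saturation → adipose/pseudo-green.  No stain
deconvolution or normalization is attempted — the synthetic sections have
well-separated classes, and real trichrome stains would need threshold
recalibration (the thresholds are module-level constants).  The
epicardium-exclusion mask is an *input*; epicardium detection is out of
scope.  Section fractions are pixel counts over tissue pixels (scale
invariant, so the resolution the image is loaded at does not matter) and
sum to 100 exactly.  The 360-sector overview assigns each 1° sector the
connective percentage of the section whose span contains the sector
center.

## Registration

Registration is purely rotational and acts on sector profiles, not
pixels: every downstream comparison is section-averaged, so profile-level
rotation is sufficient and exactly testable.  The mid-lateral landmark is
either supplied directly (mirroring manual selection) or derived as the
circular midpoint of the major arc between the two RV hinge angles — the
point opposite the RV.  Diametrically opposite hinges leave the landmark
ambiguous and raise an error.

Fractional-sector rotations are resampled spectrally by default (FFT
phase shift): exact for band-limited profiles, mean-preserving, and
invertible to machine precision.  The pipeline itself rotates the K=360
%TM/MSI maps with bounded circular *linear* interpolation instead,
because those maps are discontinuous at the scar border and a spectral
shift rings there (producing small negative %TM).  Nearest-sector
assignment is also available.  Section averaging weights each sector by
its angular overlap with the section span, so the span-weighted mean of
the section values equals the profile mean exactly.

## Mixed models and explained variance

Section log-fibrosis y_ij (natural log of fibrosis % plus an offset,
default 0.1 percentage points, so zero-fibrosis sections stay finite; the
offset is recorded in the table metadata) is modelled with a per-animal
random intercept, u_i ~ N(0, τ₀₀), e_ij ~ N(0, σ²).  The null model has
no covariate; each full model adds one CMR covariate.  Explained variance
is R² = 100·(1 − total_full/total_null) on the σ² + τ₀₀ totals.

* **ML vs REML.** Fits are maximum likelihood by default: the R² compares
  variance totals across models with different fixed effects, where ML
  totals are the conventional choice.  REML sits behind a flag; the
  package's own recovery validation (tests) uses REML, the unbiased
  estimator for variance components — the ML τ₀₀ mean carries the
  (n−1)/n small-sample deflation at 15 animals.
* **Boundary pooling.** When the τ₀₀ estimate falls below 1e-8, or every
  optimizer hits a singular information matrix (the variances are not
  separable), the fit is reported pooled: τ₀₀ = 0 and σ² holding the
  total unexplained variance of the fixed-effects-only fit (ML divisor
  N).  Pooled totals enter R² unchanged.  Degenerate inputs (zero total
  or zero within-animal variance) are handled in closed form.
* **Optimization.** statsmodels `MixedLM` with an optimizer cascade
  (lbfgs → powell → cg → bfgs); near the τ₀₀ = 0 boundary single
  optimizers stall or raise on a singular matrix while another converges
  cleanly.  A genuine universal failure raises, it is never silently
  absorbed.
* Negative R² (full model worse than null) is reported as-is; display
  rounding is to integer percent with full precision retained.

## Synthetic cohort: what it emulates, and what it does not

The phantom is an annular LV (endo 20 mm, epi 30 mm, 1.5 mm pixels) with
an anteroseptal scar wedge growing from the endocardium outward
(subendocardial infarct pattern) over a per-animal transmural fraction.
LGE intensity is a linear map of local fibrosis fraction onto
[remote, scar] intensity (defaults 20 → 100 a.u.) plus Gaussian noise
clipped at zero — Gaussian rather than Rician for simplicity, defensible
because only relative thresholds are used downstream.  Cine contraction
moves the endocardium inward linearly over frames toward an end-systolic
thickening profile with a 10° cosine border ramp.

Cohort defaults (chosen once as study-realistic conditions):

| parameter | default | rationale |
|---|---|---|
| animals × sections | 15 × {7, 8} | study scale, ~108–120 sections |
| transmurality | U(0.15, 0.95) | wide infarct severity range |
| scar fibrosis fraction | U(0.30, 0.57) | observed maximum ≈ 57% |
| remote fibrosis | 0.03 | healthy collagen background |
| healthy thickening | N(4, 0.5²) mm | normal systolic thickening |
| thickening loss | linear, complete at 50% transmurality | functional loss saturates once half the wall is scarred |
| WT jitter (Segment/FT) | 0.5 / 1.0 mm | contour-tracing variability |
| strain jitter (ε_cc/ε_rr) | 4 / 15 %-points | FT variability; radial strain is the noisiest export (reported SD ≈ 35%) |
| fibrosis log-noise | animal 0.25, section 0.30 SD | biological + measurement spread |

The functional measurement jitter is a fixed property of the emulated
modalities: the `noiseless()` preset zeroes the LGE image noise and the
fibrosis log-noise but keeps that jitter, because a fully deterministic
phantom would make wall thickening and strain informationally equivalent,
which real FT exports are not.

What the generator does **not** emulate: Rician noise statistics, partial
volume at the scar border, through-plane motion, contour segmentation
bias, real trichrome stain variability, or 3-D infarct geometry (one
slice per animal).  Passing tests therefore demonstrate correctness of
the measurement chain and the statistics under these idealized
conditions, not clinical performance on porcine or human data; absolute
R² values from the synthetic cohort are conditions-dependent, whereas the
qualitative ordering (LGE > thickening > strain) is the robust output.

## Numerical choices and degenerate inputs

* Sector means use exact pixel/sample tallies (`bincount`); the %TM
  export is bit-reproducible against a naive per-pixel loop.
* Missing sectors (NaN) are filled by circular linear interpolation from
  the nearest valid sectors before resampling in the pipeline.
* Equal-intensity degenerate cases: a uniform myocardium under FWHM flags
  the whole myocardium (threshold = v/2); a zero-variance remote region
  is valid (threshold = mean).
* A static cine series has no end-systole; the last frame is used with a
  warning.
* Scar width 0 means "no scar" (uniform thickening), keeping the uniform
  phantom expressible.
* All generators take explicit integer seeds; identical (spec, seed)
  pairs are bit-identical.  Cohort generation spawns one child seed
  sequence per animal, so per-animal streams are independent.

## Known limitations

* Strain is contour-geometric, not feature-tracked; torsion and
  longitudinal strain are out of scope.
* Registration corrects rotation only — no translation, no deformable
  matching, no long-axis slice matching; a residual rotational error
  between modalities is not estimated or corrected.
* The hue-partition classifier is tuned to the synthetic stain colors;
  real slides need threshold recalibration and possibly stain
  normalization.
* Only a single random intercept is supported — no random slopes, no
  crossed effects, no multiple-testing adjustment.
* User-data mode of the pipeline consumes a prepared section table;
  image-level user data is handled by composing the library stages.
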