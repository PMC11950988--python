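# Methods

## Problem and model

Early ischemic infarction lowers CT attenuation of brain parenchyma by a
few Hounsfield Units (HU).  The ASPECTS (Alberta Stroke Program Early CT
Score) quantifies early ischemic change in the middle-cerebral-artery
territory: ten regions per hemisphere — caudate head (C), insular ribbon
(I), internal capsule (IC), lentiform nucleus (L) and six cortical sectors
M1–M6 — each lose one point from 10 when affected.  A score below 6 is the
imaging contraindication for intravenous thrombolysis, so the dichotomized
flag (ASPECTS < 6) is the primary clinical output.

`aspectscore` detects per-region hypodensity by comparing each region's
windowed HU statistics against its mirror region in the contralateral
hemisphere, on the clinically affected side (laterality is an input, as it
is for a radiologist reading the study).  Two detectors are implemented:

**RELDIF** — relative mean difference.  With affected-region mean `I` and
contralateral mean `J`,

    delta_pct = 100 * max(0, (J - I) / J)

and the region is positive when `delta_pct >= Delta`, a per-region
threshold in percent.  The difference is one-sided: hyperdensity of the
affected side is floored to zero (it is not ischemia).  The contralateral
mean is the denominator.

**DDET** — density distribution equivalence test.  Pixel samples of the
left and right regions give means `I, J` and standard errors
`SE_I = SD_I / sqrt(n_I)` (sample SD, ddof = 1).  With
`SE = sqrt(SE_I^2 + SE_J^2)` an equivalence test at margin `delta_m` (HU)
is performed first:

    H0: |I - J| - delta_m = 0    H1: |I - J| - delta_m < 0
    z = (|I - J| - delta_m) / SE,    p = Phi(z)

If `p < alpha` the hemispheres are equivalent and the region is negative.
Otherwise a one-sided superiority Z test on the mean difference decides:
the region is positive only when the affected side is *significantly
lower* (`Phi^-1` tail below `alpha`).  Significant hyperdensity or
non-significant evidence both resolve to negative — the conservative
no-call default.  Degenerate inputs: `SE = 0` reduces both tests to
deterministic comparisons, with `|I - J|` exactly at the margin routed to
the non-equivalence branch; a region whose pixels are all excluded by the
HU window is "indeterminate" and scores negative but is listed in the
report.  The superiority branch reuses the one-sided `alpha = 0.05`.

The equivalence test is a single composite-null test on the absolute
difference, not a pair of symmetric one-sided tests; the two are nearly
equivalent at these SEs but the absolute-difference form matches the stated
hypotheses exactly.  Forming SE from pixel counts assumes independent
pixels; CT noise is spatially correlated, so real-data SEs are
optimistic — the margins absorb this in calibration.  This is a known
limitation.

## Standardization and segmentation

Slices are standardized before any statistic is computed: (1) HU windowing
to 10–55 HU inclusive (excludes CSF, chronic infarcts, bone and
calcification; the window flags pixels, never alters them); (2) skull
stripping by intensity threshold (default 300 HU), selecting the largest
connected above-threshold component and taking its hole-filled interior
minus all bone pixels; (3) crop to the brain bounding box, aspect-ratio
preserving rescale, and centering on a square canvas (default 256 px) with
0 HU background.  An optional 3×3 median denoise exists but is off by
default because smoothing changes the pixel statistics the detectors
consume.

Region masks come from a labeled two-slice atlas aligned to each
standardized slice by a 2D similarity transform (rotation, isotropic
scale, translation) maximizing Mattes mutual information (32 bins, dense
sampling, 3-level shrink pyramid, regular-step gradient descent).  Dense
sampling makes registration deterministic.  Because the MI landscape of
near-aligned piecewise-constant images is non-convex, the optimized
transform is accepted only if its full-resolution metric beats the
initial (centered) transform; otherwise the initial transform is kept.  A
final metric above a floor (−0.15) raises an error — structureless input
cannot be registered.  An optional coarse B-spline refinement (8×8 control
grid, same metric) models residual deformation and falls back to the
identity field when it does not improve the metric; it is off by default
since the detectors operate on region means and tolerate small boundary
error.  Labels are resampled with nearest-neighbor interpolation, and the
four internal basal-ganglia masks (C, L, IC, I) are dilated by 1 px
(configurable), clipped to the brain, with overlap resolved by nearest
original-mask centroid (deterministic, name-order tie-break).

## Calibration

Each detector has one per-region free parameter, swept on a fixed grid:
Delta over 0.05–50% and delta_m over 0.05–16 HU, both in steps of 0.05
(1000 and 320 values; grids are generated from integer indices so float
accumulation cannot change their length).  Each grid value yields one
binary operating point on a labeled calibration cohort; its AUC is the
trapezoid through (0,0), (1−spec, sens), (1,1), i.e. `(sens + spec)/2`,
making max-AUC selection identical to max-Youden.  The chosen value is the
max-AUC grid value among those with specificity ≥ 0.88; ties resolve to
the smallest value (highest sensitivity — missing an infarct is the worse
error).  If no value meets the floor, the max-specificity value is chosen
with a warning.  Calibration consumes region statistics computed from the
ground-truth atlas masks, isolating detector calibration from segmentation
error.

The shipped per-region defaults (`calibrate.default_params()`) are
reference values calibrated on a 65-patient clinical set:
delta_m = {C 3.9, I 2.05, IC 1.75, L 1.95, M1 0.75, M2 0.7, M3 0.95,
M4 0.25, M5 0.8, M6 1.65} HU and Delta = {C 9.1, I 4, IC 4.85, L 4.9,
M1 1.55, M2 1.3, M3 5.05, M4 2.3, M5 1.8, M6 3.9} %.

## Synthetic phantom cohorts

The phantom emulates exactly the features the pipeline consumes: an
elliptical brain with a 1000 HU skull ring on two slice levels, ten
bilaterally mirrored region masks (M1–M3 on the basal-ganglia level,
M4–M6 on the cortical level, the standard ASPECTS template), CSF ventricle
pockets at 4 HU so the 10–55 window has something to exclude, per-region
baseline HU in the 31–41 range (deep gray denser than cortex, internal
capsule lower — realistic contrast that also feeds the MI metric), i.i.d.
Gaussian pixel noise (default SD 1.5 HU, typical of parenchymal noise in
a standard-dose head CT), and lesions as uniform HU decrements inside a
region on one hemisphere.  One hemisphere is built analytically and
mirrored, so noiseless left/right statistics are bit-identical and an
injected decrement appears exactly in the contralateral mean difference.
The patient side of every labeled component is stored explicitly, never
inferred from array orientation.

Cohorts draw lesions independently per region with a given prevalence,
decrements uniform in a range (absolute HU or relative to baseline),
laterality as a fair coin, all reproducible from one seed.  Cohort records
carry a stroke-category tag; calibration and evaluation first drop
non-acute categories (hemorrhagic, subacute, chronic), mirroring the
clinical exclusion flow.

What the phantom does *not* model — partial-volume gradients, beam
hardening, streaks, gantry tilt, spatially correlated noise, anatomic
asymmetry — bounds what passing tests show: they verify the statistical
machinery and the geometry pipeline, not clinical performance.  Clinical
deployment requires recalibration on local data.

## Evaluation statistics

Rater comparisons use: confusion-matrix proportions (zero-denominator
ratios reported as unavailable, never 0); nonparametric ROC AUC by
midranks with the Hanley–McNeil SE; paired one-sided Z tests on per-unit
differences for equivalence (composite null on |mean difference| at margin
delta), noninferiority (H0: diff = −delta vs H1: diff > −delta) and
superiority (delta = 0), all at one-sided alpha 0.05; and Cohen's kappa
with large-sample SE, 95% CI, and Altman's qualitative bands (very good
≥ 0.81, good ≥ 0.61, moderate ≥ 0.41, fair ≥ 0.21, else poor; interval
boundaries stay in the band they close, so 0.8 is "good" and 0.81 "very
good").  The default equivalence margin for mean ASPECTS comparisons is
0.5 points (5% of the 0–10 scale), configurable.  Clustered-proportion
machinery (GEE) and multi-reader variance decompositions are out of scope;
plain proportions over per-patient (or per patient-region) units are the
analysis unit.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on phantoms:
128–256 px slices; calibration/held-out cohorts of 200 patients each
(baseline 40 HU, noise 1.5 HU, lesions 8–12% of baseline, prevalence
0.3); 1000 randomized inputs for the decision-rule oracles; 10,000 null
simulations of n = 48 for the type-I-error check; 100 random cohorts for
the monotonicity sweeps.  These sizes give stable pass/fail behavior while
keeping the full suite under a minute of compute.
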