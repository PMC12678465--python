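# Methods

## Measurement model

All inputs are linear calliper measurements in millimetres on axial slices;
no unit inference is performed. A `LinearMeasurementSet` enforces strict
positivity, finiteness, and the anatomical ordering that each ventricular
width is strictly smaller than the skull/inner-table diameter it is divided
by. The Evans denominator (maximal internal skull diameter) is carried as
its own field rather than reusing the bi-parietal diameter at the
frontal-horn level: the two are measured on different criteria and need not
coincide. Because each index is a ratio of lengths, all three are invariant
to global rescaling and lie strictly inside (0, 1) for any valid set.

Pathological classification uses a strict inequality, `value > cutoff`, for
every index. The conventional rules for MRHI (> 0.579) and Evans' index
(> 0.3) are strict, and the package applies the same convention to the
study-derived cutoffs (BLM 0.285, EI 0.280, MRHI 0.461) so that a value
exactly at a cutoff is never called pathological.

## Landmark geometry

A measurement may be supplied as a pair of 3-D points, in world RAS
millimetres or voxel indices. Voxel points are mapped through the 4×4
homogeneous affine (taken from the NIfTI-1 header when a volume is given;
voxel intensities are never read) and the measurement is the Euclidean
distance between the mapped points. Distances are invariant under rigid
motion of the world frame to < 1e-9 mm. Coplanarity with an axial slice is
deliberately not enforced — annotations may be oblique — but a pair spanning
more than 2 mm in world z triggers a logged warning, since the indexes are
defined on single axial slices. The skull slice for the MRHI denominator is
not inferred; it must be supplied as its own landmark pair.

## Statistics

**ROC.** The positive class is iNPH and higher index values are more
iNPH-like. Candidate thresholds are the midpoints between consecutive
distinct scores plus a below-minimum and an above-maximum sentinel; a
subject is called positive when its score strictly exceeds the threshold.
This produces exactly the confusion counts attainable by thresholding at
observed values while being stable under ties. AUC is the trapezoid of the
(FPR, TPR) polyline, which for finite samples equals the Mann–Whitney
statistic U/(n₁n₂) with ties half-credited; the suite verifies this
equivalence against brute-force pair counting to 1e-12, and checks the
binormal limit Φ(Δμ/√(σ₁²+σ₂²)) on large simulated Gaussian arms.

**Youden cutoff.** The reported cutoff maximizes J = TPR − FPR; ties are
broken by highest sensitivity, then lowest cutoff. Tie detection uses a
1e-12 tolerance on J so that operating points whose J values are equal as
exact rationals (but differ in the last float bit) are treated as tied; the
test oracle re-derives the optimum with exact rational arithmetic. When no
threshold discriminates (max J = 0) the below-minimum sentinel is returned
with a degenerate flag.

**Group comparisons.** Each continuous variable passes through a
Shapiro–Wilk gate at α = 0.05 per group (scipy's Royston implementation,
3 ≤ n ≤ 5000; for larger groups the gate runs on a deterministic 5000-point
subsample). Both groups normal → two-sided unpaired t-test; otherwise
two-sided Mann–Whitney U using the tie-corrected normal approximation
without continuity correction — group sizes in this design (tens per arm)
are comfortably asymptotic, and no exact enumeration is attempted.
Proportions use Pearson's chi-squared without Yates continuity correction
(df = 1). Percentages in rendered reports are rounded half-up to one
decimal; JSON output keeps full precision, and p-values below 0.001 render
as "< 0.001".

**Logistic regression.** Diagnosis (iNPH = 1) is regressed on age, sex and
one index at a time, by IRLS with at most 100 iterations and convergence at
max |Δβ| < 1e-8. Wald z and p-values come from the inverse observed
information. Separation is flagged when any standardized coefficient
magnitude (|β|·SD of the covariate) exceeds 15 or when the log-likelihood
stabilizes while coefficients keep growing; the fit is still reported, with
a warning that its p-values are unreliable, rather than silently switching
to a penalized estimator. On a cohort in which an index separates the
groups perfectly — which the default simulation parameters make likely for
BLM — this flag is the expected and correct outcome. Non-convergence
without separation raises an error.

## Synthetic cohorts

The generator's defaults are the published group-level characteristics of
the clinical sample: 35 iNPH vs 39 PSP; BLM 0.332 ± 0.04 vs 0.234 ± 0.02;
MRHI 0.533 ± 0.050 vs 0.419 ± 0.038; EI 0.341 ± 0.05 vs 0.233 ± 0.02; age
74.5 ± 7.1 vs 69.4 ± 7.7 years truncated to (30, 100); male proportions
0.714 vs 0.385; PSP split 24 PSP-RS : 15 PSP-P with phenotype-specific BLM
0.230 ± 0.021 and 0.240 ± 0.019 (the mixture reproduces the arm-level
0.234 ± 0.02 within rounding). Standard deviations are taken literally as
printed.

Indexes are truncated Gaussians on (0.05, 0.60), sampled by rejection.
For BLM and EI the bounds sit many standard deviations from the means and
the truncation bias is below 0.1%; the iNPH MRHI arm, however, has its
upper bound only 1.3 SD above the mean, so its truncated mean is ≈ 0.524
rather than 0.533. The parameter-recovery tests therefore compare simulated
moments against the analytic truncated-normal moments, which is the exact
property of the sampler; the configured-value recovery claim is asserted
only where the truncation is genuinely negligible (BLM, EI).

Indexes are independent across subjects' panels by default, matching the
fact that only marginal moments are published. An optional shared latent
"ventriculomegaly factor" with configurable loading λ (0.7 suggested)
induces a cross-index correlation of λ² for users who want realistic
positive dependence; no test asserts a particular correlation.

`measurement_level` mode additionally inverts each index panel into a full
measurement set: skull and inner-table diameters are drawn from adult
priors (bi-parietal 115–140 mm, bi-temporal 100–130 mm, skull 115–150 mm)
and the ventricular widths are solved so the recomputed indexes match the
targets to 1e-9, with plausibility caps on widths (e.g. FH ≤ 70 mm) and a
preferred 60:40 occipital:temporal split of the BLM remainder, clamped to
the caps. Denominator draws are retried up to 50 times before a target is
declared infeasible, so only systematically impossible panels (e.g.
EI = 0.99) fail. What the simulation does **not** model: within-subject
anatomical covariance beyond the single latent factor, longitudinal change,
scanner and site effects, and measurement error in the callipers — passing
tests on simulated cohorts therefore demonstrate correctness of the
pipeline arithmetic under the stated distributional assumptions, not
clinical performance on real images.

## Pipeline behaviour at the margins

The study workflow requires both groups present. Below three subjects per
group the Shapiro–Wilk gate is impossible; comparisons then fall back to
Mann–Whitney without the gate, the logistic fit is skipped (n < 10), and
the report carries explicit unreliability warnings — a deliberate
degradation so that smoke-scale cohorts still produce a complete, flagged
report instead of an error. Reports are pure functions of their inputs:
identical records and options yield byte-identical JSON.

## Problem sizes

Large-sample checks (parameter recovery, the binormal AUC limit, the
acceptance script's simulated mean) use 2×10⁴–10⁵ subjects per arm, sizes
at which the Monte-Carlo standard error of a mean is an order of magnitude
below the asserted tolerances; property sweeps use 200 random samples of
n ≤ 50, where brute-force all-pairs oracles are exact and cheap.
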