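# Methods

This note documents the models, parameter choices and known limitations
of the package, in the order the pipeline runs.

## Synthetic phantoms

The phantom is a schematic brain: an ellipsoidal tissue support on a
40×48×40 grid of 4 mm voxels (≈ 27k brain voxels) carrying 17 box-shaped
parcels — the 14 analysis ROIs (calcarine, cuneus, superior/middle/
inferior occipital, fusiform, lingual, inferior/middle/superior
temporal, precuneus, DLPFC, posterior cingulate, angular) plus three
auxiliary parcels (superior parietal, frontal eye field, premotor/motor)
needed by the classification rules.  Only the topological relations the
rules rely on are guaranteed: occipital parcels posterior, DLPFC
anterior, posterior cingulate and precuneus medial, lateral parcels
mirror-symmetric about the midsagittal plane.  Parcels are separated by
≥ 2-voxel (8 mm) gutters so that 8 mm smoothing of a planted effect in
one composite cannot drag a neighbouring composite over the involvement
threshold.  The default grid keeps a single-subject GLM at well under a
tenth of a second, which is what makes the 100-subject and
leave-one-out simulations in the test suite practical; the grid is a
parameter and scales up freely.

Uptake is modelled as `g · template · (1 + s·N(0,1))` inside the brain
and 0 outside, with:

* `template` = 1 everywhere in brain (gray-matter elevation optional,
  default 0), times an optional linear age modulation of gray matter
  (slope per year relative to age 64.68; default 0).  The age effect is
  deliberately regional so that it survives global mean scaling and
  genuinely exercises the nuisance covariate — a purely global age
  effect would be removed by scaling and could not distinguish the
  age-corrected from the uncorrected model.
* `g` — subject-level global uptake factor, log-normal with log-sd 0.2,
  standing in for injected dose / metabolic rate differences.  It
  multiplies signal and noise alike, so it cancels exactly under global
  mean scaling.
* `s` — voxel noise, sd expressed as a fraction of local tissue uptake,
  default 0.05.

Patients apply per-ROI fractional uptake reductions to the template.
The default templates encode the four canonical topographies: DLB-like
(occipital 25%, temporo-parietal 20%, precuneus 20%, DLPFC 15%,
posterior cingulate spared), AD-like (temporo-parietal, posterior
cingulate and precuneus 25%, occipital spared), PCA-like (occipital 30%,
temporo-parietal 20%, frontal eye field 25%, applied fully in one
hemisphere and divided by the asymmetry factor in the other, DLPFC
spared), PD-like (premotor/motor 25% only).  No quantitative effect
sizes exist for these patterns in the clinical literature the package
follows; the 15–30% range is a calibration choice giving voxel t values
of roughly 15–25 against a 112-control database — comfortably
suprathreshold, as clinical single-subject maps are — and it is fixed
once here, not tuned per experiment.  The asymmetry factor defaults
to 8: with Bonferroni thresholds near t ≈ 5.4 and post-smoothing noise
near 1%, the contralateral reduction (30%/8 ≈ 4%) stays subthreshold, so
the planted asymmetric pattern actually yields an asymmetric
suprathreshold map.  This was chosen from the threshold arithmetic, not
fitted to test outcomes.

Cohort defaults mirror the emulated clinical series: 112 controls aged
64.68 ± 9.35 (truncated at 18), 72 DLB, 55 ADD + 5 PCA, 36 PD, with
per-group age distributions taken from the published demographics.

What the phantoms do **not** emulate: PET physics (scatter, attenuation,
partial volume, reconstruction artifacts), anatomical variability and
registration error, atlas boundary uncertainty, and correlated
(non-white) physiological noise.  Passing tests therefore demonstrate
the statistical machinery — covariate handling, error control, rule
logic, recovery of planted effects — not clinical performance on real
scans.

## Preprocessing

Gaussian smoothing at 8 mm isotropic FWHM (σ = FWHM / 2√(2 ln 2),
converted to voxels), computed with reflective boundary handling and a
6σ kernel truncation.  Reflection conserves the total image sum exactly
for a symmetric kernel and leaves constants untouched, avoiding rim
artifacts on the small phantom grid; 6σ truncation keeps the discarded
tail (~2e-9) far below the 1e-6 accuracy asserted for the kernel.

The analysis mask is built from controls only (patient hypometabolism
must not shrink the analysis domain): voxels whose across-control mean
exceeds 0.8 × the mean over positive voxels.  The 0.8 fraction is a
stand-in for the implicit masking of standard neuroimaging packages,
which is not publicly specified.

Global mean scaling multiplies each scan so its within-mask mean equals
the target.  The target is 1.0 rather than the traditional grand-mean
50: every downstream quantity is a ratio or a t statistic and is
invariant to the constant, so the simpler unit is preferred.  Scaling is
idempotent and commutes with smoothing whenever smoothing preserves the
within-mask mean (exactly true on a full-grid mask; approximate
otherwise, because the data-dependent scale factor is computed on
different images — the linearity of both operators is what the test
suite checks).

## t-maps, FWE and clusters

Per voxel OLS of uptake on [intercept, subject indicator, age], ages
mean-centered; t is the negated indicator coefficient over its standard
error so hypometabolism is positive, df = (N + n_test) − rank(X).  Only
this one-sided contrast is assessed.  Voxels fitted exactly (possible in
noise-free phantoms) are assigned t = 0 when the indicator coefficient
is also at rounding level, ±∞ otherwise, instead of dividing two
rounding errors.  A design with constant ages and the age covariate
requested is rejected as rank-deficient rather than silently dropped.

Familywise error is controlled by Bonferroni over the in-mask voxels:
the threshold is the upper-tail Student quantile at α/V.  Random-field
theory — the method historically used inside SPM — depends on smoothness
estimates and implementation details that are not reproducible from the
outside; Bonferroni is conservative, exactly implementable and
independently verifiable, and the threshold function records its method
tag so alternatives can be plugged in.  Under the spatial correlation
introduced by smoothing, Bonferroni over-corrects; the test suite checks
the empirical familywise rate on leave-one-out null controls stays at or
below nominal.

Cluster extent: connected components of {t ≥ threshold} at
18-connectivity (the convention of the reference software; 6 and 26
available), keeping components with ≥ k voxels.  The conventional
k = 100 is tied to 2 mm voxels, so the default is expressed as a
physical volume, 100 × (2 mm)³ = 800 mm³, and converted to voxels by
rounding up (13 voxels at 4 mm).  "At least k" is adopted over "more
than k" (a `strict_gt` flag provides the other reading, since the
sources state both).

## Hallmarks

"Presence of hypometabolism" in a region has no published operational
definition; it is implemented as the suprathreshold-in-cluster fraction
of the composite ROI reaching ≥ 2% (configurable).  A fraction is robust
to single stray voxels and monotone in the threshold, which the rules
rely on.

CIS is computed on the smoothed, globally scaled uptake image (not on t
values) as mean(PCC) / (mean(precuneus) + mean(cuneus)).  The sum of the
two ROI means — rather than the mean over their union — follows the
quoted formula literally and gives the 0–1 range consistent with
published cutoffs near 0.8.  The ratio is invariant to any positive
rescaling, hence to the scaling target.

The ROC cutoff maximizes Youden's J over midpoints of adjacent sorted
unique values (high CIS = positive class); ties break toward higher
sensitivity, then the lower cutoff.  AUC uses the Mann-Whitney identity
with ties counting one half.

The asymmetry formula is wholly unspecified in the source material; the
package uses AI = |n_L − n_R| / max(1, n_L + n_R) over extent-filtered
suprathreshold voxels, symmetric when AI ≤ τ (default 0.5, chosen so
bilateral phantom patterns are symmetric and the hemisphere-weighted PCA
pattern is not).  An empty map is symmetric by convention.

## Pattern classification and voting

The published pattern descriptions are prototypes, not an algorithm; the
decision list in `dlbpet.patterns` is the single most consequential
reconstruction in the package.  Order: negative → PD-confined →
(occipital ∧ temporo-parietal, with the FEF/asymmetric/DLPFC-spared
sub-rule for PCA) → posterior-without-occipital AD rule → most-involved
composite with a fixed tie order (DLB > AD > PCA > PD).  The four rater
variants (involvement thresholds 1, 2, 2, 5%; asymmetry tolerances 0.4,
0.5, 0.5, 0.6) synthesize the variance of four human experts; a 3-of-4
quorum reads "supermajority" as more than a simple majority for four
raters.  Votes failing quorum return DISCORDANT with the plurality label
recorded for adjudication.  Because the variants are deterministic
functions of the same profile, their agreement on clean synthetic data
is near-perfect — the published human κ ≈ 0.8 is not a reproducible
quantity and is not targeted.

## Diagnostic statistics

Pairwise cohort evaluation excludes subjects labeled with a third
pattern (e.g. AD-like DLB patients in the DLB-vs-PD comparison): this is
the only reading that reproduces the published DLB-vs-PD sensitivity of
1 with a 0.94 lower bound (an exact lower bound of 0.94 pins n = 64,
i.e. the 8 AD-like cases removed) together with the published
accuracies.  Proportion intervals are Clopper-Pearson exact; Pearson
chi-square is uncorrected (matching the published 8.887 and 8.276
exactly); McNemar is continuity-corrected (matching 12.03 under the
reconstructed discordant counts 5 and 25); report comparison rounds
half-up to 2 decimals.  Two published interval endpoints (0.70 for
31/36; 0.53 for 81/132) differ from the exact bound by one unit in the
second decimal and are reproducible by no standard interval; the
acceptance tests hold them to ±0.011 and every other figure to printed
precision.  The DeLong test uses the structural-component covariance
estimator, returning Z = 0, p = 1 for degenerate variance.  Group
comparisons of continuous clinical features use Welch's t by default
(the published analysis does not state equal-variance or not; summaries
and raw samples give identical results through either entry point).

## Subtyping

Features are mean unthresholded t per ROI over in-mask voxels —
unthresholded, so severity below the FWE threshold still informs the
clustering.  Columns are standardized before PCA (the source analysis
does not say; standardized is the common default and is configurable),
and the smallest number of components reaching 80% cumulative variance
is kept.

Clustering applies the Lance-Williams Ward recurrence to squared
Chebyshev (supremum-norm) dissimilarities.  Ward on a non-Euclidean
dissimilarity is formally improper — merge heights lose their
within-cluster-variance meaning — but this exact combination is the
analysis being reproduced, so it is implemented faithfully (and agrees
with an independent implementation of the same recurrence to machine
precision).  Heights are reported on the square-root scale of the
recurrence and are non-decreasing; ties break toward the lowest cluster
indices.  The number of clusters is a parameter (the emulated analysis
reports a 2-cluster solution); mean silhouette scores for k = 2…6 are
available as guidance, not as an automatic selector.  Flat cuts label
subgroups by decreasing size.

Binary clinical features are compared between subgroups with the
uncorrected Pearson chi-square on reconstructed counts (percentage × n
rounded to nearest integer — validated to reproduce both published
chi-squares), continuous features with Welch's t.

## Problem sizes used in validation

The shipped tests and the acceptance script run: a 112-control /
100-patient classification cohort; 200 (tests) or 100 (script)
leave-one-out null subjects for the familywise error rate; 50 (tests) or
10 (script) seeds of two 20-subject planted subtype cohorts against 40
controls.  These sizes give binomial standard errors small enough for
the stated bounds while keeping a full run in the minutes range on one
CPU.

## Known limitations

* The phantom geometry is schematic; results quantify the statistical
  machinery, not clinical accuracy.
* Bonferroni FWE is conservative relative to random-field or
  permutation methods; sensitivity bounds here do not transfer to
  noisier real data.
* The decision list and the asymmetry index are documented
  reconstructions, not published algorithms.
* Published image-level results that depend on the undeposited clinical
  scans (the 41/31 subgroup split, the CIS cutoff 0.82, κ = 0.80,
  DeLong Z = 3.01) are out of reach by construction and are not
  asserted anywhere.
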