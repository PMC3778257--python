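# Methods

This note documents the models, conventions and numerical choices behind
`wmvpa`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

A cohort of N subjects with mesial temporal lobe epilepsy is described
by (i) a smoothed white-matter (WM) tissue-probability volume per
subject and (ii) a binary post-surgical outcome label: +1 favorable
(ILAE classes 1–2), −1 non-favorable (classes 3–6). The task is to
predict the label of an unseen subject from the volume alone, to
quantify the uncertainty of the achieved accuracy honestly at small N,
and to interpret the classifier spatially and clinically. Template
registration, tissue segmentation and bias-field correction are outside
the package's scope: inputs are assumed to be already-segmented WM maps
on a common grid.

## Synthetic cohorts

The generator emulates the *statistical* structure of smoothed WM
segments, not brain anatomy. Per subject, a volume is built as

    baseline (+ delta inside each planted sphere, positive class only)
    + iid N(0, noise_sd) voxel noise  →  Gaussian smoothing  →  clip [0, 1]

Noise is added **before** smoothing so the output has the spatial
autocorrelation of real smoothed segments. Clipping reflects that WM
intensities are tissue probabilities. Planted effects are spheres with a
signed intensity offset `delta` between class means; each sphere must
lie entirely within one hemisphere. Hemisphere convention (used
consistently by the lateralization module): the first voxel axis is
left–right and indices below the midpoint are LEFT; for an odd first
axis the exact midplane belongs to neither hemisphere.

Defaults, chosen once as a plausible small-cohort study condition:
16³ voxels of 2 mm (a down-scaled whole-brain grid), baseline intensity
0.55, noise SD 0.05, smoothing FWHM 3 mm, 10 + 10 subjects. "Strong
signal" experiments use `delta = 3 × noise_sd = 0.15`, sphere radius 3.
Clinical covariates are drawn from simple marginals (discrete-uniform
ages with onset ≤ MRI ≤ surgery, Bernoulli febrile history, log-normal
seizure frequency, follow-up floored at 12 months per the usual
inclusion criterion); only marginal plausibility is intended, no claims
about real covariate distributions or their correlations.

What passing tests on these cohorts do **not** show: robustness to
registration error, scanner/site effects, anatomically realistic effect
geometry, or class overlap structure of real patient data.

## Gaussian smoothing

Isotropic-in-mm Gaussian kernel, per-axis
`σ_vox = FWHM / voxel_size / (2√(2 ln 2))`, truncated at 4σ and
**renormalised per output voxel** (the filtered volume is divided by the
filtered all-ones volume). This makes the operator exactly
constant-preserving at edges and linear — the two properties the test
suite pins down — at the cost of slightly inflating values near
boundaries relative to plain zero-padded convolution.

## Analysis mask

Real studies use a registered anatomical WM mask; as a configurable
stand-in the package masks to voxels whose cohort-mean intensity exceeds
0.05, which removes empty background and nothing else on synthetic data.

## Fisher-criterion selection

Scores are `f_v = (μ̂+ − μ̂−)² / (σ̂+ + σ̂−)` with **population** (divide
by n) class standard deviations and the **sum-of-σ̂** denominator.
Both choices are switchable (`sd="sample"`, `denominator="variance"`):
the criterion is only used for *ranking*, where the flavors rarely
disagree, but the printed form is the default. Zero-denominator voxels
get score 0 when the class means agree, else the maximum finite score —
this keeps the ranking total. Ties in the ranking break by ascending
column index, making selection fully deterministic.

## Linear SVM

Standard soft-margin primal, linear kernel, no feature standardisation
(intensities already share the [0, 1] scale; configurable upstream).
Training is delegated to the libsvm solver; the fitted model is stored
in primal/dual form (w, b, per-subject α ∈ [0, C]) and the test suite
independently verifies, on randomized instances, the KKT conditions,
the representation identity `w = Σ αᵢ yᵢ xᵢ`, and objective equality
with a brute-force dual quadratic program (SLSQP with multiple starts)
on instances of ≤ 6 points. A decision value of exactly 0 predicts −1:
the conservative (non-favorable) clinical call, fixed here because the
sign rule is otherwise defined only by strict inequalities.

## Nested LOSO cross-validation

Outer loop: each subject held out once; inner loop: LOSO over the
remaining N−1 subjects, evaluating every (C, k) grid cell with Fisher
scoring and top-k selection recomputed inside each inner fold on its own
N−2 subjects. The inner metric is balanced accuracy over the inner
out-of-fold predictions, matching the headline metric under class
imbalance. Ties break toward smaller k then smaller C (sparser,
smoother models). Inner folds whose training remainder is single-class
are skipped and the metric renormalises over realised folds. The
leakage invariant — corrupting a held-out subject's features changes
neither that fold's (C*, k*) nor its selected columns — is asserted
exactly in the tests.

Default grid: C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} (the libsvm convention),
k ∈ {10, 20, 50, 100, 200, 310, 360, 500}. The simulation experiments
use reduced grids so each experiment is a subset of the same search
space: nulls use C ∈ {2⁻⁵, 1, 32, 1024}, k ∈ {10, 100} on 12³ cohorts;
strong-signal runs use C ∈ {0.1, 1, 10}, k ∈ {10, 50} on 16³ cohorts.

A caveat worth knowing: on *null* data, a grid containing only small C
values degenerates to majority-class prediction, and because each
held-out subject is the training minority in balanced LOSO designs this
yields systematically below-chance accuracy (the well-known LOSO
anti-learning artifact). With a C range available, the inner search
avoids those cells — degenerate cells score 0 on the inner folds too —
and null cohorts calibrate near chance, slightly below 0.5 on average.

The discrimination map is produced by a **single all-data refit**
(hyperparameters re-selected by the same LOSO search over all N
subjects), with a fold-averaged map available as an alternative, since
either reading is defensible for a published map.

## Evaluation conventions

All confusion-derived identities are computed on integer counts. The
**reported** balanced accuracy is the sample value (sens + spec)/2; the
**credible interval** comes from independent Beta posteriors with
uniform priors, `Sens ~ Beta(TP+1, FN+1)`, `Spec ~ Beta(TN+1, FP+1)`,
`B = (Sens + Spec)/2`, central interval by Monte Carlo (default 10⁶
draws, seeded). The split matters: at these cohort sizes the posterior
mean of B sits several points below the sample value, and only the
sample value matches the conventional headline numbers. AUC is the
rank statistic (ties ½), which equals the trapezoidal area under the
empirical ROC. PPV is undefined (NaN) when no subject is called
positive. For comparison with printed clinical tables, percentages are
rounded half-away-from-zero to integers and ratios to two decimals.

## Lateralization and clinical statistics

Chi-square tests on the discrimination map use df=1 goodness-of-fit
against an even 50/50 split, no continuity correction, computed on
voxel **counts** by default (the natural χ² object) with |weight| sums
behind a flag; the choice is recorded in outputs because either unit is
a defensible reading of a published "weighting distribution".

Fisher's exact test is two-sided by the minimum-likelihood rule (the
dominant convention; verified against full enumeration in the tests).
Mann-Whitney U uses the exact null distribution when there are no ties
and min(n) ≤ 12, otherwise a normal approximation with tie correction
and a centered continuity correction (|U − mean| reduced by ½, floored
at 0, so identical samples give p = 1 exactly). Kruskal-Wallis is
tie-corrected with a χ² reference. "Support-vector weighting" for the
covariate correlations means the out-of-fold decision-value magnitude
(the per-subject quantity a study can print); the dual-coefficient
reading is available via `weighting="alpha"`. The SV vs non-SV
comparison partitions subjects by α > 0 in the final refit crossed with
outcome and reports degenerate partitions as such.

## Packaged fixtures

The per-patient decision tables (19 males, 30 females) and clinical
tables ship as CSVs so the evaluation layer runs offline. One
documented correction: female subject F19 is recorded with the
non-favorable label implied by her ILAE outcome class 3 (the printed
decision table carries a favorable label inconsistent with the
published sensitivity/specificity); the printed value is kept in a
`label_printed` column. The clinical tables are shipped exactly as
printed, including one subject whose surgery age precedes the MRI age,
and fixture loading therefore does not enforce the synthetic generator's
age-ordering invariant.

Known non-reproducibilities from the printed values, excluded from the
acceptance computation: the published AUCs (0.93/0.95) differ from the
rank AUC of the printed decision values (0.943/0.981 — the original ROC
construction is unrecoverable); the female febrile Fisher p (0.71; the
minimum-likelihood convention gives 1.0 for those counts); the
lateralization χ² p-values (the weighting unit is unstated); and the
310/360 optimal voxel counts (data-dependent outcomes of the original
MRI).

## Problem sizes in tests and the acceptance script

Null calibration: 20 cohorts of 10+10 subjects on 12³ grids. Strong
signal: one cohort of 10+10 on 16³. Credible-interval coverage: 1000
simulated confusion matrices at true (sens, spec) = (0.9, 0.8) with
n = (11, 8), 2×10⁴ posterior draws per interval. These sizes are
package defaults chosen to make the full suite comfortably re-runnable
on a single CPU while leaving the measured quantities stable to well
within the asserted bands.
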