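# Methods

`psmalesion` implements a lesion-based analysis of PSMA-targeted PET/CT
performed before and after [177Lu]Lu-PSMA-617 radioligand therapy (RLT) in
metastatic castration-resistant prostate cancer. The unit of analysis is a
single metastatic lesion observed on two scans; the scientific question is
how well baseline uptake (SUV_max, SUV_mean, tumor-to-liver ratio) predicts
which lesions will be refractory to therapy.

## Lesion quantification

**Fractional isocontour.** A lesion is segmented as the set of voxels at or
above 40 % of its maximum SUV, restricted to the 26-connected component that
contains the peak voxel. The peak is searched inside a user-supplied voxel
box (replacing the manual VOI placement of clinical practice with an
explicit, reproducible seed); component growth may extend beyond the box and
is clipped only by the grid. Conventions, all configurable or at least
explicit because the field does not standardize them:

- threshold comparison is inclusive (`>= fraction * SUV_max`), so boundary
  voxels behave deterministically;
- connectivity is the 26-neighborhood, which avoids splitting blurred peaks
  into face-connected fragments;
- argmax ties break toward the lowest linear index;
- the fraction is relative to the lesion maximum, making the mask invariant
  under global rescaling of the volume.

SUV_mean is the mean over the mask; by construction `suv_mean <= suv_max`
and every mask voxel is at least `fraction * suv_max`.

**Liver reference.** The liver SUV_mean is averaged over a 30 mm-diameter
spherical VOI; a voxel belongs to the sphere when its *center* lies inside.
A sphere that would be clipped by the grid raises a geometry error rather
than silently truncating, because a partial VOI biases the reference.
Volumes are axis-aligned SUV grids (`world = origin + index * spacing`);
NIfTI affines with rotation or shear are rejected explicitly rather than
resampled.

## Per-lesion metrics and classification

- **TLR** = lesion SUV_max / liver SUV_mean of the same scan;
  post-treatment TLR uses the post-treatment liver value, since the liver
  reference is re-measured on every scan.
- **V-score** (E-PSMA 4-point visual scale): 0 strictly below blood pool,
  1 above blood pool but ≤ liver, 2 above liver but ≤ parotid, 3 above
  parotid. A lesion exactly at the blood pool scores 1 (score 0 is defined
  strictly as "below blood pool"); the score is monotone in uptake.
- **Response category**: RL (responding) if SUV_max declined ≥ 30 % *or*
  the post-treatment V-score is 0; otherwise PL (progressive) if SUV_max
  rose ≥ 30 %; otherwise SL (stable). Both 30 % boundaries are inclusive,
  and the V-score-0 arm takes precedence even over a nominal SUV increase —
  the response definition is a disjunction, and organ references can shift
  between scans. Percent change is computed on SUV_max only; SUV_mean is
  carried descriptively.
- Lesions missing post-treatment values are excluded with a logged reason;
  they are treated as V-score-0 responders only when an explicit
  `post_undetectable` flag says the lesion vanished, because the pipeline
  performs no lesion re-identification. All reported fractions use the
  classified set as the single denominator.

## Threshold and ROC statistics

**Stratification.** At a TLR cutoff *t*, lesions split into `TLR < t`
(test-positive for predicting progression) and `TLR >= t`. PPV is the
progressive fraction below the cutoff, NPV the non-progressive fraction
above; empty strata yield undefined (NaN) predictive values, never 0.

**Odds ratio.** OR = ad/(bc) on the (progressive / non-progressive) ×
(below / above) table, with the Woolf logit 95 % interval
`exp(ln OR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d))` and a two-sided p-value
from the Woolf z statistic. Zero cells receive the Haldane–Anscombe +0.5
correction and the result is flagged. No continuity correction is applied
to nonzero tables: that choice reproduces all four published confidence
intervals to two decimals, which is the evidence it was the original
method.

**ROC.** Low uptake predicts progression, so the classifier score is the
negated metric. AUC is the tie-corrected rank statistic (equal to the mean
pairwise concordance with ½ credit for ties, verified against exhaustive
pair enumeration). The operating cutoff maximizes Youden's
J = sensitivity + specificity − 1 over rules "progressive if metric <
cutoff", candidates being the observed values plus +∞; ties in J resolve
toward higher sensitivity — conservative for a rule meant to catch
refractory lesions.

Rank correlations (Spearman mid-ranks), Mann–Whitney U (exact for small
tie-free samples, tie-corrected normal approximation otherwise) and the
paired t-test (used for liver-reference stability across scans) follow
their standard definitions via scipy. Reported tables round percentages to
whole numbers and ORs/CIs to two decimals, matching the display convention
of clinical threshold tables; exact values are always emitted alongside.
Since the published association between baseline uptake and "lesion
response" never defines the response coding, the package computes Spearman
correlations between each baseline metric and the percent SUV_max
*decline*; signs should be read with that orientation in mind.

## Synthetic cohort generator

The generator emulates the structure of a 61-patient mCRPC RLT cohort:
per-patient lesion counts log-normal around a median of 12 (minimum 3),
site mix 70.6 / 25.2 / 3.1 / 1.1 % (bone / lymph node / visceral /
primary), baseline SUV_max log-normal with median 14.1 and log-SD 0.76,
and organ references (blood pool 1.8 ± 0.15, liver 4.1 ± 0.30, parotid
15 ± 2 SUV) drawn per patient and timepoint. SUV_mean is modelled as
0.62 × SUV_max with 5 % relative noise — a modelling convenience consistent
with the ratio of the cohort medians, not an imaging-physics claim.

**Response model.** The true category of each lesion is drawn from a
continuation-ratio (sequential) logistic model in x = log TLR:

    P(respond)                = expit(0.12 + 1.00 x)
    P(progress | no response) = expit(−0.04 − 1.29 x)

This parameterization always produces a valid probability vector and is
monotone: hotter lesions respond more and progress less. A single
proportional-odds (shared-slope cumulative) model cannot simultaneously
match the overall category mix and the sub-liver stratum mix, which is why
the sequential form was chosen. The default coefficients were obtained once
by numerically integrating the model over the baseline TLR distribution and
solving for an overall RL/SL/PL mix of 77/17/6.5 % together with a
TLR < 1 stratum mix of 45/22/33 % — the magnitudes at which liver-derived
thresholds are debated clinically. They are ordinary configuration fields,
not constants. Given the category, the post/baseline SUV_max multiplier is
drawn from per-category distributions (responders `0.7·Beta(1.2, 1.8)`,
stable `0.7 + 0.6·Beta(2, 2)`, progressors `1.3 + Gamma(1.5, 0.5)`) so that
re-classification recovers the true category except in the rare case of a
faint stable lesion dropping below the blood pool. The strength of the
coupling between baseline uptake and response depth is a calibration
choice: real cohorts report only a weak-to-moderate rank correlation, and
nothing in the public record pins down the joint distribution.

Randomness is a single root `numpy` SeedSequence with per-patient spawned
sub-streams, so a fixed seed yields byte-identical tables and patient
subsets are reproducible independently of cohort size.
`expected_category_mix` integrates the response model over the TLR
distribution (Gauss–Hermite over the liver jitter, dense grid over log
SUV_max) and serves as the independent expectation in recovery tests.

**What the generator does not emulate:** scanner reconstruction, partial-
volume effects, intra-patient correlation of lesion responses beyond the
shared liver reference, site-specific uptake differences, new-lesion
formation, and patient-level outcomes. Passing recovery tests therefore
demonstrates that the statistical machinery is correct under the stated
generative model — not that the clinical effect sizes are reproduced from
raw images.

**Phantoms.** `generate_phantom` builds sphere-plus-liver-block scenes
(voxel-center membership), applies a Gaussian PSF (FWHM/2.3548 → σ) *before*
additive Gaussian noise — the physical order of resolution loss and count
statistics — and returns ground-truth masks and SUVs. Phantom quantification
recovers peak SUVs within 10 % for lesions with radius ≥ 2 × PSF FWHM.

## Reference dataset

`datasets.synthetic_reference_cohort()` expands published aggregate counts —
response totals per site and response counts in nested TLR strata at
cutoffs 1.00/1.50/1.76/2.00 — into a 718-row synthetic per-lesion table.
Each stratum's lesions carry one representative TLR strictly inside the
stratum and placeholder SUVs (liver fixed at 4.1); category is encoded as a
fixed post/baseline multiplier (0.5 / 1.0 / 1.5). Classifying this table
reproduces the published stratified statistics exactly, because those
statistics depend only on the stratum × category counts; medians of the SUV
columns are artifacts and must not be interpreted.

## Numerical conventions and problem sizes

Quantiles use linear interpolation (type 7). Percentages round to the
nearest whole number for display. Test and acceptance runs use cohorts of 12–80
patients (a few hundred to ~1100 lesions) and phantom grids up to 48×24×24
voxels, which keeps the full suite to a few seconds while leaving all
statistics well inside their asymptotic regimes; the generator scales to
arbitrarily larger cohorts unchanged.

## Known limitations

- No partial-volume correction, CT co-registration, or DICOM handling;
  volumes must already be in SUV units on axis-aligned grids.
- The blood-pool ROI convention is unspecified in the field; the package
  takes blood-pool values as given inputs.
- ROC cutoffs and AUCs on synthetic cohorts characterize the generator, not
  any clinical population.
- Patient-level endpoints (PSA response, survival, new-lesion progression)
  are out of scope by design.
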