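# Methods

This note documents the models, conventions and numerical choices behind
`vftrial`, and what the synthetic machinery does and does not establish
about real perimetry data.

## 24-2 geometry and area bookkeeping

The 24-2 grid is generated row-wise: rows y = ±21° carry x ∈ {±3, ±9};
y = ±15° carry x ∈ {±3, ±9, ±15}; y = ±9° and y = ±3° carry
x ∈ {±3, ±9, ±15, ±21}. That yields 52 common-frame points — 26 per
hemifield, 13 per quadrant. Each eye-native grid adds the two nasal points
at (∓27°, ±3°) and removes the two temporal blind-spot points (±15°, ±3°),
keeping 52 measured locations per eye. One point stands for a 6° x 6° =
36 deg² cell, which fixes the improved-area arithmetic (2 points = 72 deg²,
3 points = 108 deg²; a full hemifield saturates at 936 deg²).

Coordinates are visual-field space (+x right, +y superior) for both eyes;
the left eye's grid is stored natively, not mirrored, so a location means
the same direction of gaze for either eye.

## Binocular integration

Integrated sensitivity is the pointwise maximum over eyes. TD and the TD
probability category are carried from the eye that supplied the maximum
(ties to the right eye) rather than re-derived, because the defect mask is
defined on TD probability and must live on the integrated map; the
alternative (pointwise max of TD) was considered and rejected since TD and
sensitivity winners can disagree when the eyes differ in age-normative
level. At blind-spot points the fellow eye's value stands in unmodified —
no interpolation. Nasal |x| = 27° points are single-eye and asymmetric, so
they are excluded from the common frame and all scoring regions.

## Outcome definitions

- **Defect mask**: baseline locations with TD probability category
  strictly below 5. Categories encode the tightest level at which a point
  is abnormal (0.5, 1, 2, 5; 100 = within normal limits), so the strict
  rule keeps the 5% category itself out of the mask.
- **Classification**: side is the strict-majority hemifield of the mask
  (an exact tie is refused as un-lateralized); hemianopia requires both
  quadrants of that hemifield to be ≥ 25% defective (≥ 4 of 13 points),
  otherwise quadrantanopia in the dominant quadrant (tie to the upper).
  The threshold operationalizes an ophthalmologist's judgment and is
  configurable.
- **Improved area**: a location counts when its sensitivity gain is
  ≥ 6 dB *and* its baseline sensitivity is below a 30 dB normal threshold
  — already-normal points are not improvable (pass `normal_cap_db=None`
  to disable). The 6 dB criterion is roughly twice the test-retest
  variability of automated perimetry. Gains are computed on the 0 dB-floored
  sensitivity scale the exams report.
- **Defective hemifield** for outcomes is the *full* 26-point hemifield on
  the classified side, not the mask alone, so boundary points contribute
  to both improved area and MTD.
- **Responder**: strictly positive regional MTD change.

## Statistics

All tests delegate to scipy.stats with the variants pinned here:

- Pearson chi-square on 2x2 tables **without** Yates correction (with the
  correction the published baseline-table p-values .85/.23 are not
  reproduced).
- Fisher exact, two-sided by the probability-mass rule — the sum of
  hypergeometric probabilities (fixed margins) not exceeding the observed
  table's. The suite verifies this against a from-scratch enumeration for
  all tables with n ≤ 60.
- Mann–Whitney U: exact enumeration when both groups have n ≤ 8 (a full
  permutation enumeration when ties block the closed form), otherwise the
  tie-corrected normal approximation with continuity correction.
- Wilcoxon signed-rank drops zero differences (Wilcoxon's rule) and is
  undefined when all differences are zero.
- The Shapiro–Wilk gate (α = 0.05) is applied to paired differences for
  within-arm tests and to each arm's deltas for between-arm tests; a
  comparison is parametric only when no gated sample rejects normality.
  Degenerate (constant) samples route nonparametric; an all-zero
  difference vector yields "no test applicable" rather than an error at
  the report level.
- Reported p-values use the two-decimal style with `<.001` / `>.99`.

The primary between-arm comparison of improved areas is always
Mann–Whitney (improved areas are 36 deg²-quantized and heavily tied;
normality is not a tenable default).

## Synthetic cohort

The generator produces the statistical structure the pipeline assumes; the
normative surface, defect depths and quantile mapping are modelling
conventions (real perimeters use proprietary normative databases), kept in
`CohortConfig` so they are fixtures rather than claims.

- **Normative sensitivity**: 33 − 0.5·ring − 0.1·max(0, age − 45) dB,
  ring = Chebyshev ring index 0–3, clamped to [20, 40]. It reproduces the
  qualitative eccentricity and age fall-off of published normals; it is
  not fit to any database.
- **Defect template**: affected hemifield/quadrant redrawn from
  Uniform(0, 8) dB, with the |x| = 3° column as a Uniform(8, 18) dB
  transition band at the vertical meridian. At the default 3 dB normative
  SD every affected point lands in the deepest (<0.5%) probability
  category, so classification is exact in expectation.
- **Measurement**: sensitivity = clamp(truth + N(0, σ), 0, 50) with
  σ = `noise_sd_db` = 3 dB per point — half the 6 dB change criterion,
  matching the rationale that 6 dB roughly doubles test-to-test
  variability. TD probability categories come from the lower-tail normal
  quantiles of a 3 dB normative SD, so a truth-at-normative point is
  flagged ~5% of the time by construction.
- **Arms and dropout**: `n_per_arm` is exact (defaults 40/35, the
  completer counts the analysis uses). The assignment sequence uses
  1:1 permuted blocks until one arm's quota is exhausted, then fills with
  the other arm — mirroring enrolment closing earlier in one arm while
  keeping final counts fixed. The unconstrained
  `permuted_block_randomize` (balanced complete blocks, random partial
  block) is exposed separately. Dropout is Bernoulli per arm (defaults
  1/41 and 3/38); dropouts have no week-12 exams and are excluded from
  scoring, reproducing a completers-only analysis.
- **Effects**: per arm, each defective-hemifield point truly improves with
  probability `p_improve` by N(gain_mean, gain_sd) dB floored at 0.
  Defaults (NV 0.10, NV-C 0.08, gains 8 ± 2 dB) give expected hemifield
  MTD changes of ~0.8 and ~0.64 dB — the order of magnitude a modestly
  effective training produces — and improved areas a little above the
  noise floor. Both eyes share one truth map (homonymous defects) with
  independent measurement noise.

**What passing tests show.** With σ = 0 the pipeline recovers programmed
improved-point counts exactly; with σ = 3 dB a no-effect cohort produces
26·P(Z ≥ 6/(3√2)) ≈ 2.04 spuriously improved points per hemifield
(~73 deg²), and the suite checks the Monte-Carlo mean against this closed
form and the primary comparison's type-I error against 5% (2000 simulated
null trials, tolerance 2 Monte-Carlo SEs; the null-trial fields are
simulated vectorized with the same rule the scorer applies, and every
p-value comes from the package's own Mann–Whitney routine). None of this
validates the invented normative surface or defect phenotypes against real
perimetry — only the pipeline's arithmetic, calibration and invariances.

## Training simulator

Scheduling follows the deployed protocol exactly (64 x 6 x 5 x 12). Task
choice is uniform per block (patients chose freely; no structure is
claimed). Hemifield choice is stochastic with odds 4.3:1 (frequency ratio,
not a deterministic cycle). NV placements are uniform over the chosen
quadrant's grid cells with ring eccentricity 5–21° (12 of 13 cells —
only the innermost (±3, ±3) point is excluded); the per-quadrant
frequency weighting of the deployed software is simplified to uniform
between the two quadrants of the chosen hemifield (a config hook exists).
NV-C placements are continuous-uniform over the quarter-disc of Euclidean
radius 5°. The exact peripheral placement geometry of the deployed
stimuli is not public; these are configurable stand-ins.

The observer is a guessing-corrected logistic psychometric:
P(correct) = 0.5 + (0.5 − λ/2)·logistic(β·(S − θ)) with defaults β = 0.4,
θ = 15 dB, λ = 0.02; with probability λ/2 no response occurs (scored
incorrect, so the unconditional correct probability equals the formula).
Response times are Uniform(300, 3000) ms. Optional learning adds a fixed
dB increment per week at that week's trained locations. All of this is
test plumbing with no claim of biological fidelity; difficulty staircases
are not modelled.

Performance-vs-outcome association uses Spearman rank correlation between
(last-week − first-week) task accuracy and improved hemifield area, and
declines to report a coefficient when either variable is constant.

## Problem sizes and numerical notes

Monte-Carlo checks use 600 patients for the noise-only null (3 SE
tolerance on a ~0.056 SE), 2000 trials for type-I error, and 10⁵ draws
for placement frequencies (binomial SE of the 4.3 ratio ≈ 0.035) — sizes
at which the targeted tolerances are comfortably resolvable on one CPU in
seconds to minutes. CSV floats are read with round-trip precision so
write→read is bit-lossless. Exam validation is strict (complete native
grid, sensitivities in [0, 50], categorical probability codes); scoring
refuses empty regions, empty masks and un-lateralized defects rather than
guessing.

## Known limitations

- TD probability categories are consumed as given (or generated by the
  quantile convention); no normative database is re-derived.
- The SITA thresholding staircase, fixation losses and false
  positives/negatives, perimetric learning effects, and 10-2/30-2
  patterns are out of scope.
- Binocular integration is the max rule only; no summation models, and no
  Esterman binocular testing.
- The classification rule is a deterministic stand-in for expert judgment;
  borderline masks (e.g. exactly tied hemifields) are refused, not
  adjudicated.
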