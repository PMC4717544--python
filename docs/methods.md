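# Methods

## The displacement index

A bar's position is summarized by one distance per radiograph: sternal
reference point to the upper bar border, in mm, on the lateral projection.
For a series D₀ (baseline, the day after surgery) and follow-ups D₁…D_k the
package computes two signed indices,

* upward index `bdi_up = max(0, (D₀ − min Dᵢ)/D₀ × 100)` — the distance
  shrank, the bar moved up;
* downward index `bdi_down = min(0, (D₀ − max Dᵢ)/D₀ × 100)` — the distance
  grew, the bar moved down;

and the per-bar severity score `magnitude = max(bdi_up, −bdi_down)`, the
largest absolute deviation from baseline. The baseline itself is never a
candidate for the extreme. Both indices are ratios of distances, so the
score is invariant under any positive rescaling of the radiographic
calibration and under permutation of the follow-up order. A bar with
`bdi_up > 0` and `bdi_down < 0` moved in both directions; the direction
label uses a configurable minimum deviation `epsilon` (percent, default 0:
any nonzero deviation counts).

Assumptions: measurement error of the distances is not modelled (distances
are taken as given numbers); the baseline is the earliest measurement, with
a logged warning if it falls more than 3 days after surgery; series may have
any number (≥ 1) of follow-ups at arbitrary day values.

Patients with two parallel bars are aggregated by the worst bar
(`patient_magnitude`, rule `max`, with `mean` as an option). The worst-bar
rule is the clinically conservative choice: a patient is flagged if either
bar crossed the threshold. The ROC unit of analysis is the bar by default
(`--unit patient` switches), since displacement is a property of a bar and
the grading applies to the displaced bar.

## Grading and groups

The four-grade scale is encoded as a priority rule over the clinical flags:
organ compression → grade 4, correction necessary → grade 3, displacement
with external morphologic change → grade 2, otherwise grade 1 (this includes
displacement *without* morphologic change). Two implications are enforced on
input: organ compression presupposes displacement, and "correction
necessary" presupposes a morphologic change. The rule is total and monotone
on the 9 valid flag vectors. Grades 1–2 map to group A, 3–4 to group B;
group B is the positive class of the ROC. Labels can alternatively be taken
from the recorded reoperation outcome (`label_by="reoperated"`) for cohorts
where grade-3 patients declined surgery.

## ROC, interval, cutoff

Candidate thresholds are the distinct observed scores plus one sentinel
above the maximum; prediction is positive when score ≥ threshold, so the
published cutoff is itself an attainable observed value. Sensitivity and
specificity are kept as exact count ratios (k/n, not 1 − k'/n) so that
mathematically tied Youden values compare as exactly equal across
thresholds. The AUC is the trapezoidal area of this empirical curve, which
equals the Mann–Whitney concordance probability with ties counted ½.

The default interval is DeLong's: midrank placement values per positive and
per negative unit, sample variances S₀₁/m + S₁₀/n, normal interval truncated
to [0, 1]; the test of AUC = 0.5 uses the same standard error. With zero
variance at AUC ∈ {0, 1} the interval degenerates to a point (warning, not
an error). The alternative is a stratified percentile bootstrap (classes
resampled separately, seeded, default 2000 replicates).

The operating point maximizes Youden's J over the curve's thresholds. Ties
are broken toward higher sensitivity and then lower threshold — missing a
bar that needs reoperation is the costlier error; because sensitivity is
non-increasing in the threshold, both preferences select the same point. A
curve whose best J is ≤ 0 (e.g. all scores tied) has no informative
operating point and the sentinel is reported with a warning.

At n_pos ≈ 10 positive bars (the study's 7 reoperated patients), the
sampling standard deviation of the empirical AUC is large — about 0.06–0.08
for a true AUC near 0.86 — so single-cohort AUCs at this scale scatter
widely; the acceptance script reports the across-seed stability explicitly
rather than pretending to a precision the design cannot give.

## Fisher exact test

The two-sided 2×2 Fisher test is computed by direct enumeration of the
hypergeometric support under fixed margins, with log-factorial point
probabilities and the minimum-likelihood two-sided rule: the p-value sums
all point probabilities ≤ the observed one, with a relative tolerance of
1e-7 in the comparison to absorb floating-point noise among exactly tied
tables. This convention reproduces the published group-comparison p-values
(0.5856, 0.4288, 0.2414) to four decimals from the printed counts; mid-p and
tail-doubling variants do not. The test suite checks the implementation
against an exact rational-arithmetic enumeration for every table with grand
total ≤ 40.

Continuous group comparisons use the pooled-variance Student t (not Welch),
df = n₁ + n₂ − 2: on the published rounded summaries the pooled t lands
nearer the printed p-values, though exact reproduction from rounded means
and SDs is impossible and is not promised. Tertile tables use classical
one-way ANOVA for continuous covariates and the Pearson chi-square (no
continuity correction, warning when an expected count is < 5) for
categorical ones. The Haller-index change is reported as pre − post, the
sign under which the published magnitudes are positive. No multiplicity
adjustment is applied; the significance threshold is 0.05.

## Tertiles

Bars are sorted by (magnitude, bar_id) — the stable key makes ties
deterministic — and cut into three consecutive groups whose sizes differ by
at most one (30/30/30 at the study's 90 bars). Boundaries are reported as
the maximal magnitude of tertiles 1 and 2.

## Synthetic cohorts

The generator emulates the study's design, not any patient's data:

* **Composition.** 61 patients; 29/61 with double bars (90 bars); 7/61
  reoperated. These are allocated exactly (`round(n·fraction)` patients via
  a seeded permutation) rather than by per-patient coin flips, so the default
  composition is reproduced deterministically at every seed.
* **Covariates.** Group-conditional normals set to the published means ± SDs
  (age 14.0 ± 7.5 vs 23.3 ± 12.0 years; height 1.5 ± 0.3 vs 1.6 ± 0.3 m;
  BMI 18.2 ± 2.8 vs 19.5 ± 2.4 kg/m²; pre-HI 4.0 ± 1.1 vs 5.0 ± 1.0;
  post-HI 2.7 ± 0.4 vs 3.2 ± 0.5), truncated at physiologic bounds (age
  3–40 y, Haller index > 1) by resampling. Weight is derived as
  BMI × height² so the record-level consistency invariant holds by
  construction. Sex (54/61 male) and pectus type (32/61 symmetric) are
  cohort-level Bernoulli draws.
* **Displacement scales.** Per-bar target |BDI| ~ Normal(4.0, 3.0) for
  group A and Normal(10.2, 5.0) for group B, truncated at 0 by resampling.
  The separation is calibrated through the binormal identity
  AUC = Φ(δ/√(σ_A² + σ_B²)) to the published discrimination of 0.858;
  `binormal_auc` exposes the closed form as the analytic oracle for
  recovery tests. Because of the truncation the realized group mean is the
  truncated-normal mean, slightly above the configured one when the scale
  puts mass below zero; tests compare against the analytic truncated mean.
* **Trajectories.** Baseline D₀ ~ Normal(50, 8) mm; the target deviation is
  planted at a uniformly chosen follow-up day; earlier days ramp toward it
  and later days hold 50–100% of it, both with 20% multiplicative noise
  clipped so nothing overshoots the planted extreme — the realized
  |BDI| equals the drawn target exactly, and the min/max logic is exercised
  by construction. Direction is upward / downward / both with probabilities
  42/90, 27/90, 21/90; "both" bars get a secondary opposite deviation of
  20–80% of the primary at another day.
* **Grades.** Reoperated patients are grade 3 or 4 (3/7 urgent), others
  grade 1 or 2 (8/54 moderate), with flags set accordingly, so group labels
  are always consistent with grades.

What the generator does **not** emulate: measurement error on distances;
correlation between body size and displacement (the study observed heavier,
taller patients in the top tertile — covariates here are independent of the
bar trajectories given the group); within-patient correlation of two bars;
any difference between grade-1 and grade-2 displacement magnitudes; the true
(unknown) distribution family of BDI, for which the truncated normal is a
declared stand-in. Passing tests on these cohorts therefore validate the
pipeline's arithmetic and its behaviour at the study's sample sizes, not the
clinical validity of the threshold on new patients.

## Numerical and design choices

* Exact count ratios for sensitivity/specificity; trapezoid via
  `np.trapezoid` over points ordered by false-positive rate.
* Fisher via `math.lgamma`; p clipped to ≤ 1.
* Zero-variance t-test conventions: equal means → p = 1, unequal → p = 0
  with a warning.
* CSV interchange is comma-separated UTF-8 with a header, floats in
  shortest round-trip representation, parsed back with
  `float_precision="round_trip"`, so write→read is the identity and output
  is byte-stable under the fixed column order.
* All randomness flows from a single integer seed per entry point
  (`numpy.random.default_rng`); the pipeline logs stage tags and seeds.
* Problem sizes used by the checks: 100 seeds × (61 patients / 90 bars) for
  threshold stability, 10,000 single-bar patients for binormal-AUC recovery,
  1000 simulations at 50/50 for DeLong coverage, every 2×2 table with total
  ≤ 40 for Fisher enumeration equivalence.

## Known limitations

* The published AUC interval (0.769–0.923) was produced by unnamed SAS
  machinery; with the raw data unavailable, no interval method here claims
  to reproduce those endpoints.
* Printed p-values from rounded summary statistics (e.g. age p = 0.0062)
  are approximately, not exactly, recoverable.
* The chi-square p-values in tertile tables are asymptotic and unreliable in
  sparse grade rows (a warning is emitted); the study's sparse tables have
  the same caveat.
* Per-bar ROC treats bars of one patient as independent units, as the
  published analysis appears to (N = 90); the per-patient unit is provided
  as the alternative.
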