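# Methods

This note documents the statistical procedures `midkit` implements, the
design choices that were genuinely open, the synthetic-cohort generator's
model, and what the test suite does and does not demonstrate.

## 1. Data model and change scores

A paired cohort has one row per patient: baseline and follow-up values per
metric, baseline and follow-up scores per change-threshold anchor, and a
0/1 one-year survival flag. All change scores are `follow-up − baseline`,
everywhere; the direction of benefit is carried as metadata
(`direction_of_benefit = +1` for RVEF, `−1` for RV volumes) and resolved
through signs, never by re-subtracting in the other order. The relative
change is `Δ / baseline`; at a baseline of exactly zero it is flagged
undefined (NaN), never silently zero, and such patients are excluded from
the relative-scale analysis with a logged count.

Missing anchor scores are handled pairwise-complete per anchor: a patient
contributes to an anchor's analysis only with both timepoints present.
This mirrors the differing anchored sample sizes of registry practice
(e.g. quality-of-life scores introduced partway through recruitment).

## 2. Anchor classification

For a change-threshold anchor with threshold `t` and beneficial sign `s`
(−1 for emPHasis-10, where lower is better; +1 for the shuttle walk),
a patient with anchor change `d` is

* improved iff `s·d ≥ t`,
* worsened iff `s·d ≤ −t`,
* stable otherwise.

A change whose magnitude exactly equals the threshold counts as changed:
published anchor thresholds are themselves minimal important changes, so
reaching one is meaningful. (Boundary handling is a package decision; the
alternatives differ only on a measure-zero set for continuous scores.)
The three labels always partition the patients with complete anchor pairs.
The survival anchor labels every patient survivor / non-survivor; both
groups must have at least two members or downstream estimators refuse.

## 3. Correlation screen

A metric–anchor pair is admitted to MID estimation iff the Pearson
correlation between metric changes and anchor changes satisfies
`|r| > 0.20` on pairwise-complete pairs. The magnitude is used because a
negative correlation (volumes falling as a lower-is-better score improves)
is exactly as informative as a positive one. Pearson (not rank)
correlation is used, without p-values: the screen is on magnitude, not
significance. The six-unit z-score normalisation (both series rescaled so
their range spans 6 units, the quality-of-life threshold width) is
provided for reporting parity; since it is affine, screening on raw or
normalised changes provably gives identical decisions, which a property
test asserts. The exact construction of the 6-unit scale (span 6 rather
than sd 6) is a package choice and cannot affect any result.

The survival anchor has no continuous change score to correlate, so it
admits a metric iff that metric passed the screen for at least one
change-threshold anchor — consistent with screening language that excludes
a failing metric "from further MID analysis" altogether.

## 4. The four estimators

With `Δ` the change scores of the anchored (complete-pair) sample:

* **0.5sd**: `0.5 × sd(Δ within the improved group)` for improvement,
  worsened group for worsening. Sample sd (n−1 denominator) throughout the
  package — the denominator convention is stated here because sources
  rarely state theirs.
* **MDC**: `1.96 × √2 × SEM`, `SEM = sd(Δ) × √(1 − ICC)`. The sd is taken
  over *all* patients contributing to the given anchor's analysis, not an
  improved/worsened subgroup: subgrouping is tied to the 0.5sd method
  only. The MDC does not depend on the anchor labels, so it is reported
  for both directions (signed by convention) including under the survival
  anchor.
* **Change difference**: `mean(Δ | contrast) − mean(Δ | reference)`;
  reference is the stable group (survivors for the mortality anchor, which
  defines a worsening contrast only — improvement cells are emitted as
  explicit `not_defined` rows, never silently omitted).
* **Regression**: the printed four-term equation
  `DScore = k + β_b·X_better + β_w·X_worse + β_s·X_stable` with a free
  intercept is rank-deficient, so the fit uses stable as the reference
  level (`β_s ≡ 0`): an identity-link Gaussian (ordinary least squares)
  fit of `Δ` on improvement/worsening dummies. `k` is then the stable
  group's mean change and `β_b`, `β_w` are incremental differences vs
  stable — which makes them algebraically identical to the change
  differences. The package asserts this identity (to 1e−8 over random
  datasets) rather than hiding it; the two methods remain separately
  implemented and reported because the aggregation intentionally averages
  over methods.

**Signs.** Improvement MIDs are reported in the beneficial direction of
each metric (positive for RVEF, negative for volumes), worsening MIDs in
the opposite direction; distribution-based magnitudes are signed by this
convention, anchor-based estimates keep their empirical sign.

**SEM floor.** An anchor-based estimate with `|value| < SEM` (strict
inequality) is replaced by the SEM with its sign preserved and
`floored = True`; the pre-floor value is kept in `value_unfloored`. The
rule never applies to distribution-based estimates (applying it is an
error): it exists to stop anchor-based contrasts below measurement noise
from being read as real.

## 5. Aggregation and reporting

Per metric × direction × scale, each method's estimates are first averaged
over anchors (simple, unweighted average — whether to weight anchors by n
is genuinely open; the per-method means are emitted so a different reading
is recoverable), then the headline value is the mean of the method-level
means and the min–max range of those means. The heatmap table is the
methods × metrics matrix of method-level means with an average row and
column, rows fixed in the order 0.5sd, MDC, change difference, regression.
Relative-scale outputs are percent of baseline throughout.

## 6. The synthetic cohort generator

The generator emulates a two-scan treatment-response registry cohort:

1. Each patient draws a latent class (improved / stable / worsened) from a
   mixture (default 0.35 / 0.47 / 0.18).
2. Conditional on class, the latent biological changes of all metrics and
   anchors are jointly Gaussian. Within-class metric–anchor correlations
   are *solved*, not set: the configured target is the **marginal**
   correlation of observed changes, and the generator inverts the mixture
   decomposition (within-class covariance = target total covariance −
   between-class-means covariance, divided by the mean within-class sd
   product) and validates feasibility (|ρ| ≤ 1 and a positive-definite
   joint covariance per class) before any sampling. Metric–metric and
   anchor–anchor changes are conditionally independent given class — a
   simplification: real RV volumes co-vary beyond their shared response
   class.
3. Measurement error: each metric observation is true value + independent
   Gaussian error with variance `(1 − ICC) ×` total baseline variance, at
   both timepoints, so simulated scan–rescan pairs reproduce the
   configured consistency ICC (verified against an independent ANOVA ICC
   oracle within ±0.02 at n = 5000). Observed change variance therefore
   equals latent change variance + 2 error variances; configured change
   sds are *observed*-scale and the latent sd is derived (a configuration
   whose change sd is below the error contribution is rejected).
   Anchors carry no separate error model (noise is folded into their
   change sds).
4. True metric baselines are truncated at physiologic floors (RVEF 5 %,
   volumes 20 mL, stroke volume 10 mL) by rejection sampling; the floors
   sit ≥ 2.3 sd below the means, so moment distortion is negligible, and
   they prevent near-zero baselines from exploding the relative-change
   scale.
5. Anchor scores go missing completely at random at configured rates
   (defaults reproduce availability of 118/254 and 146/254); survival is
   Bernoulli per class (defaults 0.03 / 0.08 / 0.28, overall ≈ 10 %
   1-year mortality).
6. A `heavy_tail_df` toggle (off by default) replaces the Gaussian latent
   changes by a covariance-matched multivariate t.

**Calibrated defaults.** `paper_calibrated_config()` encodes the published
group table of the 254-patient cohort: metric class means/sds from the
quality-of-life-anchored cells (RVEF 32→42 / 34→42 / 38→43, RVEDV
208→182 / 200→201 / 174→163, RVESV 146→110 / 138→122 / 112→94), anchor
trajectories from their own rows (E-10 37→21 / 29→29 / 24→37; walk
distance 249→409 / 197→196 / 259→158), and marginal correlation targets
−0.25/0.20 (RVEF), 0.28/−0.28 (RVEDV), 0.32/−0.34 (RVESV), 0.10 (stroke
volume, producing the observed screen-out). Three caveats are deliberate:
a single latent class per patient cannot match the E-10- and ISWT-anchored
tables simultaneously, so the E-10 cells win for metrics; the worsened
group's walk-distance baseline sd of 16 m is kept verbatim from the source
table although it is implausibly tight; and the source's positive
stroke-related RVESV–ISWT correlation is planted with the physiologically
coherent negative sign (screening uses |r|, so no decision changes).
Change-score sds (10 %-points for RVEF, 40/35/25 mL for volumes) are
package choices within the reported "roughly 10 to 40" band. ICC defaults
(0.96 / 0.98 / 0.97 / 0.90) are representative scan–rescan reliabilities
for automated volumetric analysis; the source cites but does not print its
values. E-10 and walk-test scores are unbounded Gaussians here, so a few
simulated scores fall outside the instruments' ranges — irrelevant to
classification, which uses changes only.

**Planted truth.** For every metric × anchor × direction the generator
reports both the latent class-mean difference vs stable *and* the
closed-form estimand of the change-difference method under observed
classification: within each latent class the (metric change, anchor
change) pair is bivariate normal, so the metric's conditional mean given
the anchor falling in a class interval is a truncated-normal regression
mean, mixed over classes by their interval probabilities. These two truths
differ materially — thresholding a noisy anchor misclassifies patients and
shrinks (or even sign-flips) contrasts — and the estimator converges to
the *estimand*, not the latent difference, which recovery tests verify
within Monte-Carlo error. An analytic two-sample standard error at the
expected group sizes accompanies each estimand.

## 7. What passing tests do and do not show

The simulation is exactly the model the estimators assume (Gaussian within
class, MCAR missingness, non-informative survival given class). Passing
recovery tests therefore demonstrates correctness of the implementation
and the internal consistency of the method chain — not robustness to
skewed changes, informative attrition, or anchor floor/ceiling effects,
none of which the generator produces by default. Monte-Carlo sizes were
chosen to keep the full suite in the tens of seconds: 200 replicate
cohorts for recovery (Monte-Carlo SE ≈ 0.5 mL for volume contrasts — mean
recovery is asserted at 3 Monte-Carlo SEs), 1000 replicates for screening
operating characteristics (the planted-r = 0.30 pass rate at the anchored
sample sizes is, analytically, right at ~0.87–0.90, so a ≥ 90 % demand at
n = 118 sits on the wrong side of the screen's true power — the package
reports the measured rates as they are), and n = 5000 for moment
calibration checks.

## 8. Numerical and degenerate-input policy

Zero-variance series, groups smaller than two, all-survivor cohorts, and
over-threshold-infeasible correlation requests raise typed errors
(`DegenerateDataError`, `GroupTooSmallError`, `ConfigError`); the
orchestrator traps estimator errors per cell, emits explicit
`error` / `not_defined` / `screened_out` rows, and never lets one cell
abort the others. Group sizes, SEM, flooring flags and the pre-floor value
are carried on every output row so any number can be audited. All
randomness flows through a single integer seed; identical seed and
configuration reproduce cohort, MID table and summary CSVs byte-for-byte.
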