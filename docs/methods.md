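# Methods

## The clinical problem and the model

Adrenal vein sampling compares aldosterone/cortisol (A/C) ratios between
the two adrenal veins and a peripheral site (IVC).  Cortisol corrects for
catheter-position dilution under continuous ACTH stimulation, which
stabilizes cortisol secretion and justifies treating it as symmetric
between sides.  The pipeline implements four layers:

1. **Index computation** (`avskit.indices`).  Per-site A/C from duplicate
   samples; SI = adrenal cortisol / IVC cortisol with adequacy at SI ≥ 3
   (inclusive, so the boundary value counts as adequate); LI =
   dominant/non-dominant A/C; CSI = non-dominant A/C / IVC A/C; LAV/IVC =
   LAV A/C / IVC A/C.  The reference subtype is unilateral on the dominant
   side iff LI ≥ 4 or CSI < 1, else bilateral.  The LI threshold is
   configurable down to 3 (in clinical use for offering surgery) and the
   CSI criterion can be restricted to right-dominant patients.
2. **Cut-off derivation** (`avskit.roc`).  Empirical (staircase) ROC of the
   LAV/IVC index per subtype contrast; trapezoid AUC (equal to the
   normalized Mann–Whitney statistic with ties counting one half); DeLong
   or stratified-bootstrap AUC confidence intervals; cut-off selection by
   maximizing Youden's J among operating points whose specificity exceeds
   a floor (85/90/95% tiers).
3. **Decision model** (`avskit.decision`).  The three cut-offs partition
   (0, ∞) into right / bilateral / resample / left regions; records with an
   inadequate left-sided sample short-circuit to resampling.  Cohort
   evaluation reports the confusion table, the interpretable fraction
   (share not sent to resampling) and per-class operating characteristics.
4. **Reporting utilities** (`avskit.stats`, `avskit.io`).  Resampling-rate
   arithmetic, two-proportion power calculations, Wilson/bootstrap
   proportion intervals, validated CSV I/O and JSON/text reports.

## Duplicate averaging

"Average of the two samples per site" is ambiguous between the mean of
per-sample A/C ratios and the ratio of means.  The default is the mean of
per-sample ratios when the lists are paired, falling back to ratio of means
for unpaired lists; both are exposed via `ratio_method`.  For duplicates at
the configured assay CVs the two differ by less than measurement noise.

## Constrained Youden selection

Candidate cut-offs are midpoints between adjacent distinct observed scores
plus ±∞ sentinels, so a reported cut-off never coincides with a patient's
value.  The constraint is strict (specificity > floor) by default; a
non-strict flag exists because with small groups the two coincide in
practice.  The all-negative operating point (sensitivity 0, specificity 1)
is excluded — it trivially satisfies any floor but is useless as a
cut-off — so an infeasible floor raises an error naming the maximum
attainable specificity.  J ties are broken toward **higher specificity,
then higher sensitivity**: the floor exists to limit false-positive surgery
referrals, so when two operating points buy the same J the model prefers
the safer one.

## Contrast schemes

With a single monotone score, a one-vs-all contrast for the *middle*
(bilateral) group is structurally handicapped: the right-sided group always
lies below it, so high specificity is unreachable.  The default
`sequential_pairwise` scheme therefore evaluates right vs (bilateral +
left), bilateral vs left, and left vs bilateral, mirroring how the regions
are read off the axis; `one_vs_all` is available for comparison and
propagates its infeasibility honestly.  Derived boundaries must satisfy
right < bilateral-upper ≤ left, otherwise a threshold-ordering error is
raised rather than silently emitting an unusable table.

## Boundary convention

Published cut-off tables mix "<1.2" and "≤1.2" style comparators.  The
package uses half-open regions closed on the left — [0,1.2), [1.2,2.4),
[2.4,4.4), [4.4,∞) — which guarantees a partition; the right-closed
alternative is available and every `Decision` records the convention used.

## Synthetic cohort generator

The generator emulates a 54-patient cohort (28 bilateral, 15 unilateral
left, 11 unilateral right) whose group-wise LAV/IVC and LAV A/C summaries
are published as medians and IQRs:

| group | LAV/IVC median [IQR] | A/C median [IQR] |
|---|---|---|
| unilateral right | 0.6 [0.1–1.0] | 0.9 [0.4–2.0] |
| bilateral | 2.1 [1.7–3.2] | 3.8 [2.8–9.3] |
| unilateral left | 4.8 [3.2–5.9] | 10.6 [5.5–15.3] |

Per group, (LAV/IVC, LAV A/C) are drawn from a bivariate log-normal with
`mu = ln(median)` and `sigma = ln(q3/q1) / (2 z_0.75)`: the median and the
quartile *ratio* are reproduced exactly.  A two-parameter family cannot
match three asymmetric quantiles — the unilateral-right IQR [0.1, 1.0] is
far from log-symmetric — and `calibration_report()` prints the fitted vs
target quartiles.  Design choices:

- **Suppression-bound truncation (bilateral group).**  A bilateral label
  requires CSI ≥ 1, and CSI ≤ LAV/IVC algebraically, so genuine bilateral
  patients must have LAV/IVC ≥ 1.  The bilateral group is drawn by
  rejection above that bound, with both location parameters recalibrated
  numerically (deterministic quadrature + root finding) so the *truncated*
  medians still equal 2.1 and 3.8.  Naive rejection without recalibration
  would inflate the sample median by about 3%.
- **Correlation ρ = 0.8** between log LAV/IVC and log A/C: both are
  LAV-driven, and the implied IVC A/C (= A/C ÷ LAV/IVC) must stay
  physiologic.  ρ is unidentifiable from the printed summaries and is a
  documented free parameter.
- **RAV construction with explicit margins.**  Unilateral groups draw the
  contralateral A/C a log-uniform margin (factor 1.1–8) beyond the LI
  threshold on the intended side; the bilateral group draws it log-uniform
  inside the window where LI < 4 and CSI ≥ 1.  Truth is therefore
  unambiguous by construction.
- **Nuisance scales.**  IVC cortisol ~1000 nmol/L with 15% log-spread
  under ACTH stimulation; SI drawn uniform in [3.5, 15]; these only enter
  the analysis through ratios and are inert downstream.
- **Measurement noise.**  Duplicates are true values times
  `exp(sigma * N(0,1))` with `sigma = sqrt(ln(1 + cv^2))`, cv 5% for
  aldosterone and 4% for cortisol (within the published assay ranges).
  Because noise can push a marginal LI/CSI across its threshold, rows whose
  *measured* panel misses adequacy or the intended label redraw their
  nuisance quantities with the core (LAV/IVC, A/C) draw held fixed,
  attempt-capped.  This keeps label recovery at exactly 100% while leaving
  the group medians untouched (the conditioning only affects the thin
  near-threshold slice, far from the median).
- **Outliers.**  The published left group contains extreme values (up to
  25×); the log-normal tail produces comparable extremes naturally and no
  separate outlier mechanism is added.

`make_failed_right` removes RAV data from exactly `round(fraction·n)`
records (round-half-even), retaining labels for validation-style
evaluation.

### What the generator does and does not emulate

It reproduces group sizes, marginal index distributions, adequacy
structure, label consistency and assay-level duplicate noise.  It does
**not** model clinical covariates, imaging concordance, surgical outcomes,
inter-patient correlation structure beyond the single ρ, or the empirical
joint distribution of LI and LAV/IVC within groups (unpublished).  Passing
tests therefore demonstrate correctness of the *pipeline* under the
published marginal structure, not clinical performance on real patients;
cohort-specific quantities such as the published AUC of 0.98 for
right-sided disease depend on the unpublished joint data and are not
reproduction targets.

## Power calculation

The post-hoc design question — detect 90% vs 50% cure at α = 0.05 with 80%
power — is answered three ways: pooled normal approximation (20 per group),
Fleiss continuity correction (25 per group) and a seeded Monte-Carlo search
using the continuity-corrected two-proportion test as the oracle.  The
figure of 26 quoted in the clinical literature for this design is a
near-match to the continuity-corrected 25; no method here is forced to
output it, and reports print all three side by side.

## Numerical choices and problem sizes

- Truncated-median recalibration uses Brent root-finding with a stepped
  bracket (the profile function has a flat spurious zero in the far tail)
  and a deterministic quadrature bivariate-normal CDF, so generation is
  byte-identical under a fixed seed.
- DeLong variance uses midrank placement values; degenerate (zero-variance)
  contrasts yield a point interval at the AUC.
- Bootstrap CIs resample within class, so no resample is degenerate.
- Distribution-level tests run at 2,000–50,000 patients per group; median
  checks use the asymptotic sample-median standard error
  `1 / (2 f(m) sqrt(n))` with the (truncated, where applicable) calibrated
  density, at a 3-SE band.
- Exact A/C ties between adrenal veins leave no dominant side; such records
  are labeled bilateral with a warning (probability-zero on real data).

## Known limitations

- Empirical ROC only; no binormal/smoothed fitting.
- The exact contrast populations behind some published sensitivity/
  specificity pairs cannot be reconstructed from group sizes alone, which
  is why both contrast schemes are implemented rather than one being
  asserted as "the" published construction.
- Labels for failed-left samplings are out of scope; the decision model
  presumes an adequate left-sided sample.
- The packaged literature table transcribes published cut-offs (including
  duplicate rows that appear in the source tables) for nearest-neighbour
  comparison only; it is not a meta-analysis.
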