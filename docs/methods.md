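# Methods

## Problem and model

The package quantifies intraoperative tissue deoxygenation from multi-channel
NIRS saturation traces and evaluates each exposure measure as a predictor of
postoperative renal impairment. The signal model is deliberately minimal: a
trace is an irregular series of (time, saturation) samples in decimal minutes
from induction, with two event markers (surgical incision, end of surgery)
defining the analysis window. No smoothing, artifact rejection or drift
correction is applied — the only data-quality policy is the gap rule below.

### Baseline

The per-channel baseline is the arithmetic mean of all samples in the
`baseline_window` (default 5 min) immediately before incision. A channel with
no sample in that window has no baseline and fails loudly; nothing is imputed.

### Desaturation burdens (AUT)

For a saturation signal S(t) and level L, the area under the threshold is
AUT(L) = ∫ max(L − S(t), 0) dt over [incision, end], in %·min. Absolute
levels are 90/80/70/60%; relative levels are (1 − f)·baseline for
f = 5/10/15%. The renal-region and cerebral channels get the full grid; the
peripheral channel gets only the relative 10% level. The renal channel used
everywhere is the bilateral mean: left and right averaged at common sample
times, single-sided samples kept as-is, with the left/right Spearman
correlation of paired samples reported as a diagnostic. Unilateral records
use the available side.

### Renal-specific differential burden

Both the renal-mean and peripheral series are renormalised to
percent-of-their-own-baseline (baseline ≡ 100%); the burden is the integral
of the positive part of (peripheral − renal) on the union of the two
channels' sample grids. It is positive exactly where the renal region sits
proportionally deeper below its baseline than the periphery, and zero by
clipping elsewhere. No threshold parameter applies.

### Quadrature

Two rules are available (`integration` in `AnalysisConfig`):

* `trapezoid` (default): the clipped integral of the piecewise-linear
  interpolant, with the threshold crossing inside a sample interval handled
  exactly (the contribution of a partially-submerged interval is the exact
  triangle/trapezoid area). This is exact for the linear-interpolation signal
  model, hence agrees with a dense rectangle-rule Riemann sum as the step
  shrinks; the test suite checks agreement at dt = 0.001 min to 0.1 %·min.
* `rectangle`: left-sample deficit × interval length — the literal
  per-sample reading of the defining formula. On a uniformly sampled trace
  the two differ by O(dt); on a constant-deficit segment they coincide.

Sample intervals longer than `gap_tolerance` (default 2 min) contribute zero
burden and are accumulated into a per-result `gap_min`. Zero-filling gaps is
conservative (it can only under-count burden) and is always visible in the
output rather than silently interpolated. For the differential burden a
union-grid interval is a gap if it lies inside an over-tolerance gap of
either channel.

### Outcome rule

Renal impairment = max over postoperative days 1..7 of
(creatinine / baseline − 1) strictly greater than 0.10. The strict
inequality is enforced with a 1e-12 guard so that a mathematically exact 10%
rise (e.g. 110 vs 100) is never tipped positive by float rounding. Day-0 and
post-window values are ignored; a series with no value inside the window
raises rather than defaulting to "not impaired". Both the threshold and the
window length are parameters.

### Statistics

* Two-group continuous comparisons: Shapiro–Wilk per group at α = 0.05;
  both pass → pooled-variance t-test with mean (SD) summaries, otherwise
  Mann–Whitney U with median [IQR]. A zero-variance group routes to the rank
  test (identical constant groups short-circuit to p = 1).
* 2×2 tables: Fisher's exact test when total n ≤ 40 or any expected cell
  < 5 (Cochran's guidance), else Pearson chi-square without continuity
  correction.
* ROC: AUROC is the normalised Mann–Whitney U statistic computed from
  average ranks, identical to exhaustive pair counting with ties worth ½.
  The standard error is Hanley–McNeil's asymptotic formula; the 95% CI uses
  normal quantiles clipped to [0, 1]; the p-value tests AUROC = 0.5 against
  that SE. (DeLong variance estimation was considered and not included; at
  n ≈ 41 the Hanley–McNeil CI is the classical nonparametric default and its
  coverage is verified empirically by the recovery study.) The operating
  cutoff maximises Youden's J over midpoints between adjacent unique scores,
  ties broken toward higher specificity. A constant predictor returns
  AUROC 0.5 flagged `degenerate`.
* No multiple-testing correction is applied anywhere; the pipeline report
  instead records the number of tests it performed.

## Synthetic cohorts

The generator produces the study conditions the analysis assumes, not a
physiological simulation. Per patient:

* covariates: arm on-pump with probability 19/41; duration of surgery
  N(185, 28²) min truncated to [120, 320] and snapped to the sample grid;
  graft count in {2..5} with probabilities (7, 20, 12, 2)/41, linked to
  duration through a Gaussian copula with rank correlation 0.33; age
  N(63, 9²).
* signals, sampled every 0.5 min from induction (t = 0) with incision at
  15 min: baseline (renal N(79.5, 9.5²), cerebral N(64, 10²), peripheral
  N(84, 7²), all clipped to plausible ranges) + stationary AR(1) noise
  (sd 2%, lag-1 correlation 0.9) − Poisson half-cosine desaturation
  episodes. Episode counts are Poisson with rate per hour (renal and
  cerebral 2.0, peripheral 1.2) × a per-patient, per-channel gamma frailty
  (mean 1) × window hours; depths are Gamma (mean 10% renal/cerebral, 12%
  peripheral), durations Gamma (mean 8–10 min). A depth-D, length-L episode
  has closed-form area D·L/2, which the tests exploit.
* bilateral renal structure: both sides share the renal core process
  (baseline, dips, AR(1)) and add independent AR(1) noise (sd 1.25%) plus a
  constant side offset. The side-noise sd was calibrated once, by
  simulation, so the per-patient left/right Spearman correlation averages
  ≈ 0.80; channels other than renal left/right are mutually independent
  given the covariates.
* on-pump drift: on-pump patients get one additional half-cosine renal
  excursion of depth 12% of the renal baseline spanning a bypass interval
  (duration N(83, 22²) min), producing an on-pump excess of the
  renal-specific differential burden.
* outcome: impairment is Bernoulli with logit p = β₀ + β₁·log1p(AUT_p),
  where AUT_p is the realised peripheral rel-10% burden. β₁ = 0.5 was
  calibrated once by large-sample simulation to a designed AUROC of ≈ 0.77
  and then frozen; β₀ is solved per cohort so the mean event probability
  equals the target prevalence 0.27. The renal channels have no direct link
  to the outcome, so renal burdens are null predictors by design (a weak
  indirect association survives because all channels' episode counts scale
  with the duration of surgery — as in real cohorts, where duration
  correlates with everything).
* creatinine: baseline lognormal (median 84 µmol/l, log-sd 0.17); seven
  daily postoperative values follow a Gaussian-shaped excursion around a
  peak day in 1..5 whose height is drawn conditional on the label
  (impaired: 0.11 + Exp(0.12) relative rise, capped at 0.8; not impaired:
  U(−0.05, 0.095)) and clipped so that the label rule reproduces the drawn
  label exactly — this consistency is asserted at generation time for every
  patient.
* missingness: with probability 6/41 a renal side is dropped (unilateral
  measurement); whole-channel missingness probabilities default to 0 and can
  be raised to emulate a parent-study population with exclusions.

Determinism: one `SeedSequence` per cohort spawns a child stream per
patient, so identical spec + seed reproduce byte-identical cohorts
regardless of patient count changes elsewhere.

What the generator does **not** emulate: realistic within-channel spectral
content beyond AR(1), cross-channel episode synchrony (shared systemic
events), device quantisation (INVOS exports integer %), drug/haemodynamic
mechanisms, and informative missingness. Passing tests therefore show that
the estimators recover what this statistical regime encodes — not that the
clinical associations hold in real patients.

## Recovery study and problem sizes

`parameter_recovery_report` regenerates full cohorts (default n = 41,
prevalence 0.27), runs exclusions → panels → labels → ROC per replicate, and
summarises: mean recovered peripheral AUROC vs the designed value (computed
by simulating 4000 patients through the same link), the fraction of
replicates whose renal rel-10% CI covers 0.5, and the labelled prevalence.
The shipped acceptance script uses 200 replicates and a 4000-patient design
simulation — sizes chosen so the Monte-Carlo error of each summary is well
below the tolerances being checked while the whole study runs in seconds on
one CPU.

## Numerical and degenerate-input choices

* Burden of an empty analysis window, a trace with no baseline samples, a
  merge with no overlapping times, or a zero baseline: explicit errors
  naming the channel, never NaN propagation.
* Exactly-at-threshold samples contribute zero deficit (max(·, 0)).
* The maximum over creatinine days breaks ties toward the earliest day.
* Youden ties break toward the larger cutoff (higher specificity).
* CSV round-trips are bit-exact: values are written at full repr precision
  and re-read with round-trip float parsing.

## Known limitations

* The Hanley–McNeil CI is asymptotic; at 11 events its coverage is
  approximate (the recovery study measures it rather than assuming it).
* The gap policy under-counts burden when gaps coincide with desaturation;
  there is no imputation option.
* The generator's episode process is memoryless within a patient; real
  desaturations cluster around surgical events.
* Exclusion reasons are structural (missing channel / coverage); clinical
  exclusion criteria are out of scope.
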