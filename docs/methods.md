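# Methods

## The risk equation

The package treats the ARVC 5-year VA risk model as a *fixed*
proportional-hazards score: seven coefficients on the log-hazard scale and
a tabulated yearly baseline survival `S0(t)`. Nothing is re-estimated from
covariate data; validation asks only how well the fixed equation's
predictions, `1 − S0(t)^exp(LP)`, match a new cohort's observed event
rates. Conventions:

- **Sex** is coded male = 1 (the positive coefficient reflects the male
  predominance of arrhythmic risk in ARVC).
- **PVC count 0** is floored to 1 before the logarithm: ln 0 is undefined,
  and the floor preserves monotonicity with the count-data convention that
  the first observed event distinguishes "none" from "any".
- **Horizons** are exact-key lookups into `S0(t)`; the table is yearly and
  no interpolation is attempted between tabulated values.
- **TWI leads** are capped at 7 by default (anterior V1–V4 plus inferior
  II, III, aVF); the cap is a constructor argument (`twi_max`) because the
  exact lead set is a reporting convention, not part of the equation.
- A missing PVC count raises `MissingPVCError` rather than silently
  propagating NaN: imputation is an explicit, upstream cohort operation.

## Survival machinery

*Kaplan–Meier.* Standard product-limit estimate; at tied times events
precede censorings (the usual convention). Greenwood's formula supplies
the pointwise variance and the confidence intervals use the log(−log)
transform, which keeps them inside [0, 1] and matches the asymmetric
intervals typical of event-rate reporting; where S reaches 0 or stays at 1
the transform is undefined and the interval collapses to the point value.
Event rates are `1 − S(t)` with the right-continuous step convention; a
horizon beyond the last observed time returns the last value flagged
`extrapolated`.

*Log-rank.* Delegated to `lifelines.statistics.logrank_test`; the
degenerate no-events-anywhere case short-circuits to (statistic 0, p 1).

*Concordance.* Harrell's pairwise C over the whole follow-up: a pair is
usable when the strictly shorter follow-up ends in an event; concordant
pairs score 1, tied risk scores 1/2; pairs with identical times are not
usable. A time-dependent AUC is deliberately not used — the quantity
validated is a single per-population discrimination index. Confidence
intervals are percentile bootstrap over patients (the analytic variance of
C under censoring is awkward and the bootstrap matches the calibration CI
machinery). Tests verify the implementation against an exhaustive
pair-enumeration oracle and, on tie-free data, against lifelines (whose
convention differs only for tied-time event pairs).

## Calibration

Calibration is *cohort-level*: at each grid time t (default the yearly
grid 1–5, matching the S0 table) the mean predicted risk is compared with
the Kaplan–Meier observed rate, and the summary is the average of
(predicted − observed) across the grid. Averaging over the yearly grid —
rather than integrating over continuous follow-up — is the package's
documented choice; with a yearly baseline table any finer grid would
interpolate information the model does not contain. A grid time beyond the
last observed follow-up is dropped with a warning unless the KM curve has
already reached 0 (where S is determined). CIs are percentile bootstrap,
resampling patients with replacement (default 1000 replicates, seeded);
the point estimate is independent of the bootstrap seed. Quartile bars
split the cohort by quartiles of predicted risk at the horizon (row-order
tie-breaking keeps the partition near-equal even for a homogeneous cohort)
and report mean predicted vs KM-observed rate per quartile, flagging
quartiles whose risk set is exhausted before the horizon as unstable.

## Calibration-in-the-large

The correction is a single intercept α on the log-hazard scale: every
patient's cumulative hazard is multiplied by exp(α), equivalently
`S0_new(t) = S0_old(t)^exp(α)` at every tabulated horizon. This power
transform is exactly what makes a before/after baseline-survival table
mutually consistent (the ratio ln S0_new / ln S0_old is the same constant
at every horizon), and the package's acceptance checks verify that the
published before/after tables satisfy it.

Two estimators are provided:

- **anchor** (default): α solves
  `mean_i S0(a)^(exp(α)·exp(LP_i)) = KM(a)` at a single anchor time
  (default 5 years), by bracketed Brent root finding on α ∈ [−10, 10]
  (far beyond clinical plausibility) with tolerance 1e−10. By
  construction the average predicted survival under the shifted model
  matches the observed survival at the anchor to root-finder precision.
  Observed survival of exactly 0 or 1 at the anchor leaves α unbounded
  and raises.
- **offset**: the all-times maximum-likelihood intercept against the
  model's own baseline hazard, `exp(α̂) = Σ events / Σ H0(t_i)·exp(LP_i)`,
  with H0 the piecewise-linear cumulative hazard through the yearly knots.

The estimating procedure behind a published recalibration is rarely
reported; anchoring at the risk horizon is the default here because the
5-year probability is the quantity the equation exists to deliver, and the
two estimators agree within Monte-Carlo error on simulated cohorts (tested
at n = 2000; the discrepancy is reported, not hidden). Monte-Carlo
characterisation at n = 1000 with ~50% administrative censoring shows the
anchor estimator's bias is below 0.01 on the log-hazard scale.

## Synthetic cohorts

The generator emulates a single-centre ARVC ICD cohort. Covariates are
drawn independently — published cohort tables give marginals only, so no
correlation structure is imposed — with defaults: 71.6% male, age
42.4 ± 14.1 y (truncated at 0), 33.0% recent syncope, 50.0% NSVT history,
80.7% secondary prevention, RVEF 27.6 ± 14.4% (truncated to [0, 100]), and
a lognormal 24-h PVC count with log-median ln 1399 and
σ = (ln 2742 − ln 593)/(2 × 0.6745) ≈ 1.135, the lognormal implied by the
reported median and IQR. The TWI lead count is drawn from a distribution
over 0..7 with median 3 and IQR 2–5, matching the reported quantiles; the
exact shape within those constraints is a modelling choice.

Event times follow the proportional-hazards model exactly: the baseline
hazard is piecewise-constant between the yearly S0 knots (flat
extrapolation of the last year's rate beyond the table), each patient's
hazard is multiplied by `exp(LP + true_alpha)`, and an exponential draw is
inverted through the piecewise-linear cumulative hazard. `true_alpha`
shifts the generating process relative to the published model; 0 generates
from the model itself, and the implied secondary-prevention shift
ln(ln 0.512 / ln 0.801) ≈ 1.104 reproduces the
underestimation-then-correction pattern end to end. Administrative
censoring is uniform on (0, 10] years per patient, emulating staggered
enrolment over a ~10-year window and yielding a median follow-up near 4
years at realistic event rates; 10% of PVC counts are masked as missing by
default to exercise the imputation path (`±inf` horizon disables
censoring).

What the generator does **not** emulate: covariate correlations (e.g. RVEF
with TWI burden), informative censoring, device-programming differences,
competing mortality, or secular drift in implant indications. Passing
self-consistency tests therefore demonstrates internal statistical
correctness of the pipeline, not transportability to any real cohort.

## Pipeline

`run_validation` imputes missing PVC counts by the cohort median,
stratifies by prior sustained VT/VF into primary/secondary prevention,
computes per-stratum KM event rates (1/2/5 y), C-statistic and calibration,
fits the recalibration on the secondary-prevention stratum (configurable),
re-evaluates calibration under the shifted model, and repeats everything
with imputed-PVC patients excluded (sensitivity analysis). All randomness
flows from one seed via spawned `SeedSequence` streams, so reports are
bit-identical across runs up to their timestamp. A stratum with fewer than
two events has its metrics marked unavailable rather than failing the run.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of n = 1000–2000 with 20–50 replicates
and 100–200 bootstrap draws, sizes at which Monte-Carlo error is small
relative to the tolerances being asserted while the whole suite stays
interactive. Root finding uses Brent's method (`scipy.optimize.brentq`);
baseline-survival entries that would underflow under an extreme α are
clipped to a positive floor with a warning; model horizons are matched
within 1e−9 to absorb float round-tripping through CSV/JSON.

## Known limitations

- Calibration *slope* (and any coefficient refitting) is out of scope: the
  correction is the intercept only.
- Cardiac death / transplantation is supported only as an alternative
  endpoint label; no competing-risks estimator is provided, matching the
  separate-endpoint analysis convention.
- The C-statistic CI method differs from what any given publication may
  have used (often unstated); widths are not comparable across methods.
- The yearly S0 table makes predictions at non-tabulated horizons
  undefined by design.
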