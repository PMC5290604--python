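# Methods

## The model

`circspline` models a physiological signal observed repeatedly over 24 h —
ambulatory systolic/diastolic blood pressure is the worked domain — as a
continuous piecewise-linear function of clock time in a linear mixed-effects
model. Time is measured in half-hour slots `t ∈ [0, 48]` starting at noon,
matching a 49-reading, 30-minute monitoring protocol.

The day is divided into five segments by four interior knots: two common
clock-time knots at 18:00 and 04:00 (`t = 12, 32`), chosen where the cohort
average curve visibly bends, and two *subject-specific* knots taken from each
subject's diary (sleep onset between the common knots, wake time after
04:00). Each segment `k` contributes the broken-stick regressor

    s_k(t) = clamp(t − τ_{k−1}, 0, w_k),

zero before the segment, unit slope inside, saturated at the segment width
`w_k` after. For subject `i`, reading `j`:

    y_ij = (β₀ + b₀ᵢ) + Σ_k (β_k + b_kᵢ) s_kᵢ(t_ij) + ε_ij,
    b_i ~ MVN(0, Σ_b),   ε_i ~ MVN(0, σ² d_{g(i)}² R_i(ρ)),

with an unstructured Σ_b over intercept and slopes,
`R_i(ρ)[a,b] = ρ^{|slot_a − slot_b|}` a continuous-index AR(1) correlation
over *nominal* slot distance, and `d_g` optional residual-SD ratios per group
(reference group 1). Slopes are reported in mmHg per 30 min, so each
coefficient is directly the rate of rise or fall in its period of the day —
segment 5's slope is the morning surge, segments 2–3 the nocturnal dip.

### Periodicity constraint

A free fit does not force the mean curve to close on itself over 24 h. The
constrained variant imposes `Σ_k w_kᵢ β_kᵢ = 0`, solved for the first-segment
slope, which yields the transformed basis

    s*_kᵢ = s_kᵢ − (w_kᵢ / w_1ᵢ) s_1ᵢ,   k = 2..5.

Every `s*` column vanishes at both t = 0 and t = 48, so *any* coefficient
vector gives a periodic mean curve; this holds at machine precision and is
tested as such. Segment 1's slope is then not a free parameter. It is
reported as the constraint-implied value evaluated at the **cohort-mean
segment widths**, with an exact delta-method SE (the transform is linear in
β). Per-subject derived slopes are available through `derive_first_slope`.
The reporting convention had to be chosen because subjects have different
widths; the mean-width convention is the package's choice and is labelled
`derived` in every output. The same linear map extends the free 5×5
random-effect covariance (intercept + segments 2–5) to a derived 6×6 that
includes segment 1, again labelled rather than passed off as a free estimate.

## Estimation

Parameters are estimated by profiled REML (default) or ML. For variance
shape parameters θ the engine uses an unconstrained smooth parameterization:
`Σ_b/σ²` via log-Cholesky factors (one factor per independent random-effect
block, so a group-interaction block can be kept independent of the main
block), ρ via atanh, SD ratios via log. β (GLS) and σ² have closed forms
given θ and are profiled out. The criterion is minimized by L-BFGS-B with
the exact analytic gradient (trace identities; the envelope theorem removes
the β̂, σ̂² chain terms), from two deterministic starts:

1. a method-of-moments start — covariance of per-subject OLS coefficients,
   pooled residual variance, lag-1 residual autocorrelation;
2. an identity-scaled start (`G = 0.1 I`, ρ = 0).

A seed only matters if optional random restarts are requested, so fits are
reproducible by construction. Log-Cholesky diagonals are bounded in ±8
(variance ratios between e⁻¹⁶ and e¹⁶) to keep the boundary-variance case
(`σ²_b → 0`) numerically tame. Convergence uses L-BFGS-B's relative-change
rule (ftol 1e-9) with gradient tolerance 1e-5; the reported `FittedModel`
carries the per-start diagnostics.

Model comparison uses likelihood-ratio tests. REML log-likelihoods are not
comparable across different fixed effects, so fixed-effect LRTs (e.g. the
group × spline interaction test) always use ML refits even when headline
estimates are REML; this is deliberate and documented here because applied
reports often gloss over it. Variance-component LRTs additionally report the
50:50 chi-square mixture p-value appropriate at a boundary null.

R² follows the Nakagawa–Schielzeth decomposition with Johnson's random-slope
extension: the random-effect variance is the row-average of
`diag(Z Σ̂_b Zᵀ)`, the residual variance is the marginal `σ̂²` (AR(1)
correlation does not change marginal variance), and the fixed-effect
variance is the variance of `Xβ̂` over all rows.

Diagnostics: EBLUPs `b̂_i = Σ̂_b Z_iᵀ V_i⁻¹ (y_i − X_i β̂)` for
subject-level trajectories; the ACF of residuals pre-whitened by the
Cholesky factor of each subject's fitted marginal covariance (flat beyond
lag 0 under a correct model); and a simulation-based visual predictive
check that re-draws the response at the observed design and compares
per-slot 5–95% bands with the observed quantiles.

## Data handling

Long CSV in, one row per reading; times either numeric half-hour slots or
"HH:MM" clock strings (unwrapped across midnight so a final noon reading is
slot 48, distinct from slot 0). Day/night classification uses the half-open
diary interval `[sleep, wake)` — a reading exactly at wake time is "day", a
deterministic tie-break. Inclusion rules: at least 20 day and 7 night
readings, and no run of more than `max_gap_slots` consecutive missing
nominal 30-min slots. The default of 4 slots encodes "more than two
consecutive hourly intervals" as a 2-h span; because an hourly-bin reading
of that rule is also defensible, the threshold is a parameter rather than a
constant. Profiles without diary times are excluded by default; a
cohort-median imputation policy exists but is opt-in, because diary times
are structural (they are knots) and silent imputation would bend the basis.

## The synthetic cohort generator

No public dataset accompanies this design, so the generator is a
first-class module: 49 readings at integer slots, truncated-normal diary
times (wake 08:00 ± 1 h within (33, 47.5); sleep 23:00 ± 1 h within
(12.5, 31.5) — windows enforce the knot ordering; the source study reports
no diary-time distribution, so the spread is a choice), and the mixed-model
data-generating process above. Defaults are the published SBP estimates:
intercept 134 mmHg; slopes (0.02, −1.00, −1.93, 1.69, 2.23) mmHg/30 min;
Σ_b assembled from variances (223.6, 0.51, 0.55, 1.39, 0.66, 2.05) and the
printed correlation matrix, projected to the nearest PSD matrix if 2-dp
rounding broke positive-definiteness (for these values the projection is a
no-op); σ = 12.3 mmHg; ρ = 0.27. Optional binary group: prevalence 0.07,
additive effect 7.57 mmHg, residual SD ratio 1.09, optional per-segment
slope shifts. Covariates (age ≈ N(59.9, 5.5²) years, sex ≈ Bern(0.45), BMI
≈ N(28.5, 4.5²) kg/m²) default to zero effect on BP.

The generator is deliberately **unconstrained**: the five published slopes
do not satisfy the periodicity identity for any one width set, so they can
be used verbatim as truth. The constrained model's correctness is therefore
certified by algebraic properties (exact periodicity, constraint identity,
continuity), not by recovering a segment-1 "truth" that does not exist.

Missingness is off by default — the defaults represent a post-QC analysis
set — and is switched on explicitly (independent per-slot dropout plus
planted gap runs) to exercise the inclusion rules; the generator logs which
profiles should fail which rule, and a cross-module test holds that log to
the QC filter's actual decisions.

What the generator does **not** emulate: device error spikes, activity- or
posture-driven BP excursions, informative (e.g. sleep-related) missingness,
multi-day monitoring, or diary misreport. Passing recovery tests therefore
shows the estimator is correct *under the model's own assumptions*, not that
the model is adequate for any particular real cohort — adequacy on real data
is what the ACF/VPC diagnostics are for.

## Problem sizes in the test and acceptance runs

Simulation sizes are the package's trade-off between Monte-Carlo error and
run time: recovery experiments in `scripts/acceptance.py` use 300 subjects
(slopes, σ, ρ), 886 (group effect at 7% prevalence, the published cohort
size) and 500 (random-slope variance, R²), each a single replicate at the
full 49-slot design. The test suite's coverage experiment runs 20 replicates
at 40 subjects; LRT calibration runs 200 replicates at 40 subjects with a
random-intercept-only generator matched to the fitted null (calibration is
only meaningful when the generating and fitted models agree); VPC coverage
uses 120 subjects and 150 simulation replicates. With ~62 marked subjects
and a between-subject SD near 15 mmHg, the group-effect estimate at the
published design carries a standard error near 1.9 mmHg; its recovery check
is correspondingly interval-based (the estimate's own 95% Wald interval),
not a fixed percentage.

## Known limitations

- AR(1) distance uses nominal slot separation; an order-based adjacency
  variant (the common software default) is available for cross-checks via
  integer re-indexing but is not the default.
- Wald SEs are reported for fixed effects only; variance-parameter
  uncertainty is assessed by LRT, not intervals.
- The optimizer handles boundary variance components by letting the
  log-Cholesky diagonal hit its bound; exact zeros are therefore reported as
  ~1e-16 ratios rather than 0.
- Common knots are fixed cohort-wide (configurable, but not estimated); knot
  positions are a modelling input, not an output.
- Heteroscedastic residual groups and the independent random-interaction
  block are limited to a binary group.
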