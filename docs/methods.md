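# Methods

## The processes being modelled

An injecting career is treated as an alternating renewal process
starting in the *injecting* state at onset (day 0). While injecting, a
person is at risk of **cessation** — the start of a non-injection
period of at least 3 months; while not injecting, of **relapse** — the
end of such a period. All analyses work in **gap time**: the clock
resets to zero at the start of each episode, so the j-th episode of a
process contributes its own time-to-event, and repeated episodes within
a person are linked through a person-level random effect (frailty).

The hazard for person i during episode j is

    h_ij(t) = h0(t) · exp( x_ij(t)' β + u_i ),

with h0 piecewise-constant over gap-time intervals, x a mix of
time-constant covariates (sex; onset-age band 12–19 vs 20+; onset era,
split at 1986 when HIV testing became widely available) and time-varying
ones (current-age band <20 / 20–25 / 26–30 / 31–35 / 35+; current OST
status on/off/unknown; band of previous same-process events 0 / 1–2 /
3–4 / 5–9 / ≥10), and u_i ~ N(0, σ²) on the log-hazard scale, so
exp(u_i) is a multiplicative frailty. "σ²" reported anywhere in the
package is this log-scale variance.

### Between/within OST decomposition

If prescribing responds to a person's underlying propensity to cease
or relapse, the OST indicator is correlated with u_i ("confounding by
cluster") and its naive coefficient is biased. The remedy implemented
is covariate centering: each OST effect is split into a
between-individual term on the person's follow-up fraction with that
status (ŌST_on,i, ŌST_na,i over onset-to-interview by default; a flag
restricts to at-risk time) and a within-individual term on the current
deviation OST_ij(t) − ŌST_i. Constraining the between and within
coefficients to be equal reproduces the undecomposed model exactly;
the test suite verifies this identity numerically through the full
pipeline.

## Life-grid imputation

The questionnaire yields, per calendar year since onset: an injected
flag, the number of distinct ≥3-month non-injection periods (0–3+),
and days spent injecting. The imputation is deterministic and
single-pass, and minimizes the number of transitions:

- Years are processed chronologically. One period goes to the **end**
  of the year if the previous year finished injecting, otherwise to
  the **beginning** (so it can merge with the previous year's trailing
  period); two periods occupy beginning+end; three occupy
  beginning+middle+end. A fully non-injecting year is one period
  spanning the year.
- The year's non-injecting days (year length − days injecting) are
  split **equally** among its placed periods, each positioned flush to
  its slot; the middle slot is centred on the year midpoint and
  shifted minimally to avoid overlap. Times are kept as floats (no
  rounding), so per-year day conservation is exact.
- Periods flush to the two sides of the *same year boundary* merge
  into a single non-injection episode (one cessation + one relapse,
  never two of each). Two periods reported within one year never
  merge, even if imputed flush to each other.
- The final (interview) year is processed with the same rules over its
  truncated span; an episode reaching the interview day is censored.

Conventions for degenerate inputs: >3 reported periods are clamped to
3 with a counted warning; a year reported injected with unaccounted
non-injecting days but zero periods keeps those days as injecting
(sub-3-month abstinences were never elicited, so unaccounted days are
not evidence of cessation); periods reported with zero non-injecting
days are dropped with a warning. The first injection is anchored at
1 January of the onset year (only the year is elicited; configurable
to mid-year), and years are exactly 365 days. A cessation imputed at
day 0 yields a zero-length leading injecting episode, which preserves
alternation and episode indexing; it produces no risk-set rows but
advances the previous-event count, and enters the time-to-first-
cessation data as a zero time (admitted by default, excludable by
flag).

Minimality is verified against an exhaustive slot-assignment oracle on
random grids of up to 6 years, and the imputation recovers transition
counts exactly on constructed careers whose ≥90-day periods are
"boundary-compatible" (wholly inside a year or spanning exactly one
boundary, separated by fully injecting years, none in the final
year — an interior period there would be imputed flush to the
interview and censored, which is minimal but differs from the
constructed truth).

## Risk-set expansion

Each at-risk episode is cut at: baseline cut points (gap time), OST
status changes, birthdays crossing an age-band boundary, and
(optionally) calendar-decade boundaries — the decade covariate exists
as a recall-bias check but is off by default. Interval labels map to
days as: cessation ≤3 d, (3,7] d, (1,12] wk = (7,84] d,
(3,12] mo = (84,365] d, >1 y; relapse ≤2 mo = ≤61 d,
(2,12] mo = (61,365] d, (1,2] y, >2 y. Age at a row start decides the
age band; an exact boundary goes to the older band (left-closed
bands). OST status outside case-note coverage is coded "unknown".
Within an episode, exposures sum exactly to the episode length and the
event indicator sits only on the final row; refining any row leaves the
likelihood unchanged (tested).

## Estimation

On counting-process rows the conditional log-likelihood is the
occurrence/exposure (log-linear Poisson) form; with the baseline
log-rates entering as interval dummies, the model with σ² = 0 is
exactly a Poisson GLM with log-exposure offset, and the package's
estimates agree with an independent statsmodels GLM fit to <1e-4.

With frailty, each person's likelihood factor is an integral over u,
evaluated by **adaptive Gauss–Hermite quadrature**: per person the
integrand's mode is found by (vectorized, damped) Newton on the
strictly concave function D·u − B·e^u − u²/2σ², nodes are recentred at
the mode and rescaled by the local curvature; default order 20
(univariate), 15×15 (bivariate). Against brute-force trapezoidal
integration over u ∈ [−8, 8] with 200,001 nodes the relative error is
~1e-10, and orders 20 vs 50 agree to <1e-8.

Maximization is quasi-Newton (BFGS) over (baseline log-rates, β,
log σ²) — log σ² keeps the variance positive and unconstrained — with
the **analytic score** via Fisher's identity: the marginal score is
the posterior expectation of the conditional score, which reduces to
one weighted mat-vec per evaluation. Initial values: per-interval
events/exposure log-rates (with a +0.5/+1 smoothing), β = 0,
log σ² = log 0.25. Standard errors come from the observed information
computed by central differences of the analytic score; Wald intervals
are formed on the estimation scale and transformed (exp for hazard
ratios and σ², tanh for ρ). Zero-exposure rows are dropped with a
warning; a singular information matrix is flagged and SEs omitted.

The **joint model** gives each person a bivariate-normal pair
(u_cess, u_rel) with variances (σ²_c, σ²_r) and correlation
ρ = tanh(z), z unconstrained; the 2-D mode is found by vectorized 2×2
Newton and the integral by tensor-product adaptive Gauss–Hermite. At
ρ = 0 the quadrature factorizes exactly, so the joint log-likelihood
equals the sum of the univariate ones to machine precision — a
built-in correctness anchor. Starting values come from the two
univariate fits.

**Likelihood-ratio tests** use χ²(df) on twice the log-likelihood
difference; per-level p-values in summaries are Wald, block tests
(e.g. the 2-df within-OST block) are LR. Testing σ² = 0 sits on the
parameter boundary, so the default there is the 50:50 mixture
½χ²₀ + ½χ²₁ (a plain χ²₁ option exists since the choice is a
convention). Change-point selection is forward LR over nested
candidate cut sets at α = 0.05, returning the retained cuts and the
test trail; under a constant hazard the extra cut is retained at
roughly the nominal α, and with interval ratios of the magnitude used
by the default generator all four cessation cuts are retained at
n = 405.

## Kaplan–Meier estimation

Product-limit estimates of time from onset to first cessation and from
first cessation to first relapse (the latter among those with ≥1
cessation), with Greenwood variance and 95% intervals on the
complementary log-log scale. Quantiles use "smallest time with
S(t) ≤ q"; an unreached median is reported as such. The implementation
matches an independent reference (lifelines) to <1e-12 on random
datasets.

## The synthetic-data generator

`CareerParams` holds the generative truth; defaults describe a cohort
of 405 injectors with onset years 1970–2001 (uniform), onset ages
14–30 (uniform), 30% women, interviewed 2005–2007, matching the scale
of a long-running primary-care cohort. Covariate log-hazard ratios
default to realistic magnitudes for this population (e.g. within-OST
cessation HR 1.71, relapse HR 0.81; frailty variances 0.90 for
cessation and 0.57 for relapse; ρ = 0). Baseline interval ratios are
steeply decreasing in gap time (cessation 1 : 0.51 : 0.09 : 0.04 :
0.03; relapse 1 : 0.87 : 0.38 : 0.10); the absolute reference rates —
0.024/day (cessation), 0.00145/day (relapse) — were chosen once so the
implied marginal first-event distributions have medians of roughly
1.5 y (first cessation) and 2.4 y (first relapse) with a ~0.37
12-month relapse probability, and are not tuned thereafter.

Episodes are drawn by inverting the piecewise-constant cumulative
hazard, with the hazard updated within an episode at OST transitions
and age-band birthdays. The OST process is a two-state (off/on)
continuous-time Markov chain — mean off-spell 3 y, on-spell 1 y —
whose sojourns are masked to "unknown" with probability 0.2; any
stationary alternating process would do for testing, and the paper
trail of prescriptions it emulates carries no feedback from the
person's frailty (so the generative between- and within-OST effects
coincide). One cohort seed spawns per-person streams, so cohorts are
reproducible and insensitive to cohort size changes upstream.

Coarsening to the life grid reports, per calendar year, periods whose
**total** length is ≥90 days and that overlap the year by ≥1 day (the
3-month wording is ambiguous between total length and within-year
length; both are implemented, total is the default), absorbs
sub-threshold abstinences into injecting time, and never reports
fractional information beyond the three questionnaire fields.

What the generator does *not* emulate — and hence what passing tests
cannot show about real cohort data: recall error and heaping in the
life grids, selection into the cohort and survivor bias (only
interviewed survivors contribute), prescribing that responds to the
person's frailty (real confounding by cluster; the decomposition is
exercised algebraically, not against a feedback mechanism), mortality,
and calendar-period effects beyond the onset-era indicator.

## Known limitations

- Imputation-induced attenuation is inherent and visible in the
  round trip: coarsening hides short abstinences and the imputation
  minimizes transitions, so hazards refitted after imputation sit
  below the generative truth (the analysis drivers print both
  transition totals). Parameter-recovery checks therefore run on the
  exact simulated episodes, where the estimator is unbiased at cohort
  scale.
- The frailty correlation ρ is weakly identified when the relapse
  variance is small — as happens after coarsening+imputation under
  the default scenario — and its Wald CI on the tanh scale can be
  wide and asymmetric; the LR test is more reliable there.
- Problem sizes in the test suite (e.g. 50 replicates of n = 405 for
  recovery, 30 replicates for the joint model, 200-grid minimality
  sweeps) were chosen as the smallest that make the Monte-Carlo
  tolerances sharp; they are the package's own study sizes, not
  statements about the cohort.
- Semiparametric (Cox partial-likelihood) frailty fitting, competing
  risks/cure fractions, Bayesian estimation, and calendar-time
  (total-time) formulations are out of scope.
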