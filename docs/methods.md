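# Methods

This note documents the models, the synthetic-data design, the
numerical choices and the known limitations of phenosync.

## The scientific question and the analysis chain

A plant population's spring phenology is synchronous when its
individuals leaf out or flower within a narrow window. The analysis
quantifies synchrony per population (a 1°×1° pixel) and year as the
sample standard deviation of event dates (LOS for leaf-out, FLS for
flowering), and in parallel as the standard deviation of the degree-day
sums individuals had accumulated by their event (LOS-DD / FLS-DD). The
chain is: environmental drivers → record cleaning → synchrony series →
per-pixel regressions and cross-pixel summaries → hierarchical Bayesian
driver models, with a degree-day-only null simulation and twig-
experiment analytics alongside.

## Environmental drivers

* **Forcing (degree-days).** `DD_sum = Σ max(T_t − base, 0)` over daily
  means, base 5 °C, accumulating from 1 January for the observational
  analysis (the start date is a parameter; the twig experiments use
  10 December). Increments are clamped at zero — the standard
  growing-degree-day convention implied by calling 5 °C a *base*
  temperature; a formulation without the clamp would let warm days be
  cancelled by frost days.
* **Chilling (hours).** Each sub-daily step whose mean temperature lies
  in [0 °C, 5 °C] (both ends inclusive) contributes its step length in
  hours, from 1 November of the preceding year. A 6-hourly series
  therefore contributes 6 h per qualifying step; refinement of a
  piecewise-constant series does not change the sum.
* **Day length.** The CBM model: the solar angle
  `θ = 0.2163108 + 2·atan(0.9671396·tan(0.0086·(DOY − 186)))`, the
  declination-related angle `φ = asin(0.39795·cos θ)`, and
  `DL = 24 − (24/π)·acos[(sin 0.8333° + sin L sin φ)/(cos L cos φ)]`.
  The 0.8333° term includes civil twilight, which is why equatorial day
  length sits slightly above 12 h all year. The inverse-cosine argument
  is clamped to [−1, 1] so polar day/night return 24/0 h rather than a
  domain error. The coefficient 0.39795 is the sine of the obliquity of
  the ecliptic — the standard CBM constant.
* **Preseason temperature.** Mean daily temperature over the `window`
  (default 60) days immediately before the event anchor, excluding the
  event day. The anchor is the pixel's long-term mean event date (one
  fixed window per pixel), so year-to-year variation in preseason
  temperature reflects climate, not a moving window; a per-year-mean
  anchor is available behind the `per_year_window` flag. When the window
  reaches before 1 January it extends into the preceding December.

## Synthetic climate

Daily temperature at day-of-year *d* of year index *y*:

    T = annual_mean + warming_trend·y + offset_y
        + seasonal_amplitude·cos(2π(d − 200)/365) + ε_t

with `offset_y ~ N(0, year_offsets_sd²)` and AR(1) noise of stationary
SD `noise_sd` and lag-1 autocorrelation `noise_autocorr`, continuous
across year boundaries. Defaults — 9 °C mean, 10 °C half-amplitude,
1 °C year offsets, 2 °C noise with autocorrelation 0.7 — describe a
central-European lowland site; 0.7 is a realistic day-to-day
persistence for daily mean temperature. Sub-daily values add a diurnal
cosine (half-amplitude 4 °C, peak 14:00) whose mean over any full day
is exactly the daily mean, so degree-days computed from daily means are
unaffected while chilling hours see realistic night-time cooling. A
365-day calendar is used throughout (no leap days).

## The individual trait model

Individual *i* leafs out on the first day *t* with

    DD(1 Jan..t) ≥ max(F_i + s_dl,i·(DL(t) − 16 h)
                           + s_ch,i·(Ch(t) − Ch_ref), floor)

`F_i` is the forcing requirement under long days and full chilling
(degree-days); `s_dl,i ≤ 0` (DD per hour) raises the requirement when
days are shorter than 16 h; `s_ch,i ≤ 0` (DD per chilling hour) raises
it when chilling falls short of the reference `Ch_ref` (default
1200 h). The additive-linear form mirrors how the sensitivities are
measured experimentally — as slopes across three treatment levels — and
is a modelling choice, not an observed law; the floor (1 DD) only
guards against non-positive requirements under extreme parameter
combinations. Population defaults (forcing 105 ± 12 DD, day-length
sensitivity −12 ± 8 DD/h truncated at 0, chilling sensitivity
−0.02 ± 0.01 DD/h) put mean leaf-out near DOY 120 at latitude 48.5 in
the default climate, with strongly heterogeneous photoperiod reliance —
the within-population trait spread the twig experiments demonstrate.

This generator emulates the *statistical structure* the analysis
assumes: multi-year autocorrelated temperatures with year-level warming,
and event dates produced by trait-heterogeneous forcing requirements.
It does not emulate spatial climate fields, species-specific calibrated
traits, frost damage, observation error in the phenological scoring, or
drift/death of observed individuals. Passing tests therefore show that
the pipeline recovers the planted mechanism under its own assumptions —
not that real populations obey the linear trait model.

## Cleaning rules

Fixed order: series-SD filter → MAD filter → pixelization → panel
construction → altitude filter → coverage filter; thresholds use the
strict/non-strict inequalities exactly as stated (SD *exceeding* 25
drops; altitude deviation *exceeding* 200 m drops; coverage of *at
least* 90 % keeps). MAD is unscaled (no 1.4826 normal-consistency
factor): 3×MAD read literally is the moderately conservative screen
intended. Series with fewer than two years have undefined SD and pass
that filter; they cannot survive the shared-years requirement anyway.
Pixels are floors of the coordinates, and a boundary coordinate belongs
to the pixel it indexes — the grid origin is a convention the rules do
not fix.

Panel construction retains, per (pixel, species, phase), the largest
individual set with ≥ 15 common years: exhaustively for up to 15
candidate individuals (size-descending, ties broken by more common
years), greedily above that (repeatedly removing the individual whose
removal most increases the common-year count). The altitude filter is a
single pass against the mean of all current individuals. After the
altitude and coverage passes, panels are re-validated against the
≥ 3-individuals / ≥ 15-shared-years invariants and dropped if they no
longer qualify, so every surviving panel satisfies the invariants by
construction. The chain reports a ledger of removals per rule.

## Synchrony statistics

Sample SDs (n − 1) throughout — within-pixel n is small, and the sample
SD is the conventional estimator. Years with fewer than two observed
individuals are NaN-flagged, never silently dropped. `dl_at_forcing`
averages each individual's across-year mean degree-day sum into a
population-average requirement, finds the day that requirement is met
in each year, and evaluates day length there. Per-pixel regressions are
OLS with two-sided p-values (t distribution, n − 2 df); zero-variance
inputs raise a degenerate-input error and the pixel is excluded and
logged. Cross-pixel summaries give the mean correlation, a t-based 95 %
CI, a two-sided one-sample t-test against zero, and the percentage of
pixels with the focal sign (and with p < 0.05 in addition); no
multiple-testing correction is applied. The "95 % window" metrics model
within-pixel dates as normal, so the window spans 3.92 SD and lengthens
by 3.92·ΔSD days between a cold and a warm climate.

## Hierarchical Bayesian model

One univariate model per dependent variable:
`y_i ~ N(α + Σ β_k x_ik + u_species(i) + v_pixel(i), σ²)` with
`u_j ~ N(0, τ_sp²)`, `v_k ~ N(0, τ_px²)`. Priors: N(0, 1000) on α and
each β; Uniform(0, 100) on the random-intercept *variances* (taken
literally as variances, not SDs); vague inverse-gamma(10⁻³, 10⁻³) on
σ². A joint multivariate formulation with a correlation structure
across the four dependents is deliberately not implemented — its form
is undefined — so the four responses are modelled independently.

Sampling is Gibbs: conjugate normal updates for the coefficients and
random intercepts, conjugate inverse-gamma for σ², and shrinkage slice
sampling for the bounded-support variances (the uniform-on-variance
prior breaks conjugacy; on (0, 100] the shrinkage variant needs no
step-out and cannot escape the support). Chains are seeded by splitting
a single `SeedSequence`, so fits are bit-reproducible. Convergence is
the Gelman–Rubin potential scale reduction factor
`sqrt(((n−1)/n·W + B/n)/W)` per monitored parameter; any value above
1.1 triggers a warning, never silent acceptance. Defaults (3 chains ×
4000 iterations, 1000 burn-in) are sized for desk-scale data sets of a
few hundred rows, where the sampler mixes within seconds;
production-length chains are one argument away. Continuous variables
are standardized by centering and dividing by **two** sample SDs, which
puts effects on a comparable scale across predictors; the distribution
model used for the window metrics fits on the raw scale instead so its
slope is directly in days/°C.

With a single species or pixel the corresponding random intercept is
dropped with a warning (one level is unidentifiable), and with no
grouping at all the model degenerates to Bayesian OLS — a property the
tests exploit as a closed-form cross-check, alongside REML mixed-model
fits as an independent oracle.

## Degree-day-only null

Individuals differ only in a forcing requirement drawn once
(`N(105, 10.5²)` DD by default — 10 % relative spread, matching the
synthetic population's forcing heterogeneity); each year's event is the
fulfilment day, and per-year date SD is regressed on preseason
temperature. Requirements are fixed across years (fixed individual
differences are the premise; redrawing per year is an option for
sensitivity analysis). Event dates resolve to whole days, matching
daily climate input. Years in which any individual's requirement is
never fulfilled are flagged incomplete and excluded from the
regression; a zero-variance outcome leaves the regression
degenerate-flagged rather than raising. The coefficient this null
produces on synthetic climates is the package's own number — it depends
on the climate record used and is reported, not asserted against any
external value.

## Twig-experiment analytics

Traits per individual: forcing requirement = mean degree-days in the
fully released cell (longest chilling, 16 h days); day-length
sensitivity = OLS slope of degree-days on treatment hours at longest
chilling; chilling sensitivity = OLS slope of degree-days on chilling
hours at collection under 16 h days. Replicate summaries use the mean
of the first eight twigs to leaf out, with a flag when fewer did.

Variance partitioning offers two views. The fixed-effects view is
sequential (Type I) ANOVA sums of squares of leaf-out dates on the
three trait estimates, in the fixed entry order forcing → day length →
chilling (configurable; with orthogonalized predictors the order is
irrelevant, and near-collinearity is flagged because sequential
attribution then depends on the order). The random-effects view
estimates treatment / between-individual / within-individual components
for individuals nested within treatments by method-of-moments on the
nested-ANOVA expected mean squares (σ²_e = MS_within; σ²_ind =
(MS_ind − MS_within)/n; σ²_trt = (MS_trt − MS_ind)/(b·n)); the method
is recorded in the output, negative moment estimates are truncated at
zero and flagged, and shares are percentages summing to 100. Mildly
unbalanced tables fall back to mean cell counts; REML agrees closely on
balanced designs and serves as the independent cross-check in tests.

The nested-design generator plants variance components *exactly*: drawn
effect vectors are centered and rescaled so their sample variances
equal the nominal components. With only 8 treatments (7 df), i.i.d.
draws would make the data's realized shares differ from the nominal
ones by several percentage points from draw noise alone; planting
realized-in-data components makes recovery checks measure estimator
error, which is what they are for. Replicate noise is left as drawn.

## Problem sizes and reproducibility

Simulation studies run at desk scale as the package's own standard
conditions: mechanism recovery uses 25 seeds of one 15-individual
population over 22 years (the first year only feeds the second year's
chilling); the multi-pixel analysis uses 8 pixels; sampler calibration
uses 200-row data sets with 10 species × 20 pixels at 3 × 4000/1000
chains; the twig decomposition uses the experiment's 11 × 8 × 8 layout.
Every stochastic routine takes an explicit seed, and pipeline runs
split one global seed per stage, so all outputs are pure functions of
(configuration, seed).

## Known limitations

* The linear trait model has no interaction between day length and
  chilling, and no upper saturation; real dormancy release is nonlinear.
* Chilling uses a fixed 0–5 °C band; Utah/dynamic chilling models are
  out of scope.
* The greedy shared-years selection above 15 candidate individuals is
  not guaranteed optimal (the exhaustive path is).
* The slice-sampled variance conditionals assume the Uniform(0, 100)
  bound is generous relative to the data scale; responses whose
  random-intercept variance approaches 100 would be prior-truncated.
* Method-of-moments variance components are exact only for balanced
  designs; strong imbalance calls for REML.
* LOESS envelopes for experiment figures are not reproduced; a min–max
  envelope is the available summary.
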