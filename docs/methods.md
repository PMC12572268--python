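# Methods

`ancrain` implements a climate–health impact-attribution analysis for
routine service delivery: how much antenatal-care (ANC) utilisation is lost
to precipitation, historically and under projected climates. This note
records the model, the synthetic data-generating process, the numerical
choices, and the limits of what the synthetic experiments demonstrate.

## The two-model attribution design

The outcome is the monthly count of ANC visits y at each facility. Two
ordinary-least-squares models are fitted to log(y + ε), ε = 1 so that
zero-service months remain usable:

* **M0 (precipitation-free)** — calendar trend (year and month as single
  numeric covariates), facility setting (urban vs rural reference), zone
  (Central East reference), ownership (CHAM reference; an NGO indicator is
  optional and absorbed into the reference by default), altitude (m), and
  Euclidean distance to the closest facility (m).
* **M1 (precipitation)** — the M0 covariates plus precipitation index
  terms chosen by backward stepwise AIC from the full candidate set:
  monthly cumulative precipitation (mm), Rx5day (mm), both at lags 1, 2,
  3, 4 and 9 months, their squares (mm²), cubes (mm³), and the
  cumulative×Rx5day product (mm²).

The attributed disruption for facility i in month t is the difference of
back-transformed predictions

    ΔANC_{i,t} = ŷ0_{i,t} − ŷ1_{i,t},   ŷ = exp(Xβ̂) − ε floored at 0,

and only deficit months (Δ > 0) enter the aggregates: M0 is the expected
service volume if precipitation had no effect, so a positive difference is
the shortfall attributed to rainfall. Aggregates report the summed deficit,
its percentage of the denominator services, and the share occurring in
*extreme* months — months whose cumulative precipitation reaches the 90th
percentile of the pooled historical monthly totals (pooled over all grid
cells and months by default; a flag restricts the pool to facility-matched
cells). Scenario runs never recompute this threshold; it is anchored to the
historical window.

Deficit visits convert to affected pregnancies in either of two modes:
`per-pregnancy` divides by 4.4 visits per live birth; `per-visit` counts
each disrupted visit as one affected pregnancy. Both conventions are in
circulation and the package asserts neither as canonical.

## Climate indices

Monthly cumulative precipitation is the sum of daily values over a fully
observed calendar month (missing days are an error, never silently summed).
Rx5day is the maximum 5-day-window total with windows confined inside the
calendar month; the analysis is monthly, so cross-month windows would
attribute rainfall to two months at once. Lags are computed on each grid
cell's own calendar series and cross year boundaries; months without
sufficient lag history carry NaN and are excluded from fitting rather than
zero-filled — zero is a valid rainfall value and must not be fabricated.
Percentiles use linear interpolation between order statistics.

## Facility geolocation

Facilities are matched to grid cells by a k-d tree over the raw (lat, lon)
cell centres, ties broken toward the lowest cell index; points within half
a cell spacing of the outermost centre count as inside the grid.
Inter-facility distances use an equirectangular projection (longitude
scaled by cos of the mean latitude, 111,320 m/degree). Over a country-sized
extent any consistent planar metric preserves the covariate's information;
the constant is configurable.

## Panel cleaning

Facilities whose missing-report fraction strictly exceeds 0.9 are dropped
entirely. Missing months inside a confirmed closure range become observed
zeros (no services were delivered); an observed count inside a closure is
never overwritten. All other missingness is treated as random non-reporting
and those facility-months are excluded from fitting — no count imputation.
Missing altitudes are imputed with the mean of observed altitudes. A
collinearity screen (Cramér's V for categorical pairs, |Pearson r| for
numeric, correlation ratio for mixed; threshold 0.7) drops the designated
second member of each flagged pair — in this analysis facility type falls
to ownership and district to zone.

## Regression and selection conventions

* AIC = 2k − 2·loglik with k counting the intercept, the slopes, and the
  Gaussian error variance. The constant offset cancels in every ΔAIC the
  selector compares.
* Backward stepwise removes, at each step, the single candidate whose
  removal most decreases AIC, stopping when no removal decreases it; the
  fixed (M0) terms are never candidates. Ties in AIC improvement are broken
  by removing the term with the larger coefficient p-value, making the path
  deterministic.
* Coefficient p-values are two-sided t-tests; the M0-vs-M1 comparison is a
  likelihood-ratio test with 2(ℓ1 − ℓ0) ~ χ²(k1 − k0).
* Rank-deficient designs are rejected with the dependent columns named; the
  check runs on centred, unit-scaled columns so it is unit-invariant.
  Indicator levels with no variation in the retained rows (a level with no
  facilities, common in small simulations) are absorbed into the reference
  at design assembly, with a warning.
* Back-transformation is the naive exp(·) − ε with no smearing correction:
  the attribution statistic is a *difference* of two back-transformed
  predictions from models with near-identical residual variance, so the
  retransformation bias largely cancels; Duan smearing is available behind
  a flag for sensitivity analysis.

## The synthetic data-generating process

The generator exists so that every stage is testable without restricted
health-records data; its defaults emulate the study conditions.

**Facilities** (default 199, the study's reporting cohort) are placed
uniformly over a Malawi-sized quarter-degree extent (17°S–9.2°S,
32.6°E–35.9°E). Zones are latitude bands with an east/west split — enough
spatial coherence for zone and district covariates to behave like
administrative units, with no claim to real geography. Settings are 20%
urban; ownership is 55% Government, 30% CHAM, 5% NGO, 10% Private;
altitude is uniform on 50–1600 m, with 3% blanked in the emitted table to
exercise imputation (ground-truth counts always use complete covariates).

**Rainfall** follows a standard two-part stochastic weather generator:
Bernoulli wet-day occurrence (0.65 in the November–April wet season, 0.15
otherwise) with gamma-distributed wet-day amounts (shape 0.9, scale set so
the expected daily depth is 6 mm/day in the wet season and 0.2 mm/day in
the dry). An extreme-event mixture adds, with monthly probability 0.03 per
cell, a 200 mm burst spread over 1–5 consecutive days at a uniform start
day — by construction Rx5day responds to every burst. Cells are
independent: no spatial correlation structure is claimed or needed by the
regression, which operates per facility-cell.

**Counts** are drawn from the fitted-model form itself:
count = round(exp(Xβ + N(0, σ)) − ε) floored at 0, with σ = 0.3 on the log
scale and β the ground-truth coefficient map. The default β uses the
study-patterned values: year 0.0021, month 0.0048, urban 1.3039, zone
contrasts (Central West 0.1230, Northern −0.5623, South East 0.1036, South
West 0.0487), Government 0.2550, Private −1.8412, altitude 5e-5 per m, and
the five surviving precipitation terms (cumulative −0.0004 per mm, Rx5day
+0.0005, cumulative lag-4 −0.0002, cumulative lag-9 −0.00006, Rx5day lag-1
+0.0006). The distance coefficient is 3e-5 per metre (≈0.03 per km): a
printed per-metre value of order 1 is physically impossible for a log-count
model (a 5 km spacing would shift predictions by thousands of log units),
so the generator uses a realistic accessibility effect and documents the
choice. The intercept (0.30) puts typical facility-months in the
hundreds-of-visits range.

**Missingness** blanks facility-months independently at rate 0.35
(reproducing the study's ~⅓ unreported months) and additionally blanks all
months inside generated closure windows; the panel builder later repairs
confirmed closures to zeros. One global seed drives named substreams
(facilities / precipitation / counts / missingness / closures / altitude
masking), so each stage is reproducible in isolation and noise replicates
can redraw counts against a fixed climate.

**Counterfactual and scenario climates.** The early-period counterfactual
(default 1941–1953) reuses the generator with the wet-season mean scaled by
0.9 and the extreme-event probability by 0.25 — a record with the same
seasonality but far fewer extreme bursts, emulating a pre-intensification
climate. Future ensembles (2025–2060) scale the wet-season mean and extreme
probability upward with scenario severity (ssp126 1.00/1.00, ssp245
1.04/1.15, ssp585 1.08/1.35) and spread members by ±10% on the wet mean;
each scenario's three members are then reduced to the lowest /
median-closest / highest by grand mean monthly precipitation, so the
selection logic faces genuinely ordered members. Counterfactual
substitution maps month m of analysis year k to month m of alternative year
k (cycling when the alternative record is shorter), preserving seasonality;
scenario lag warm-up comes from the scenario's own preceding months.

## What the synthetic experiments do and do not show

Passing tests demonstrate that the machinery is correct: indices match
brute-force oracles, the regression matches a normal-equations solve,
selection paths are AIC-monotone, substituting the factual series
reproduces the factual run bit-for-bit, and a zero-coefficient
precipitation model attributes exactly nothing. Parameter-recovery runs
show the pipeline recovers known coefficients at the stated noise level.
They do not validate the study's substantive estimates: synthetic rainfall
has no spatial correlation, facility covariates explain less of the count
variance than in the real panel (so adjusted R² on synthetic defaults is
well below the study regime), and the counterfactual contrast is only as
strong as the generator's scenario severity settings. The model-difference
statistic also inherits the usual caveat of attribution-by-omission: any
signal correlated with precipitation but absent from M0 is credited to
precipitation.

Of note for interpretation: with the study-patterned coefficients the
*marginal* association of cumulative precipitation is weak (≈1 SE at the
recovery scale) because the positive Rx5day coefficient nearly cancels the
negative cumulative one in the marginal projection; the cumulative signal
is identified jointly, and with near-duplicate power terms in the candidate
set the selector reliably keeps the cumulative family but not always the
base column.

## Problem sizes

Unit and property tests run on a 20-facility, 3-year world on a 4×5×4 grid.
The parameter-recovery experiment uses 150 facilities × 48 months with 200
noise replicates. The acceptance script runs the full default study (199
facilities, 2011-01–2024-10, quarter-degree grid, three scenario ensembles
of three members over 2025–2060) plus a 40-replicate recovery summary.

## Known limitations

* Year and month enter as single numeric covariates (one coefficient
  each); numeric month is a poor seasonality model, retained because the
  analysis prints exactly one coefficient per calendar covariate.
* No facility random effects, count likelihoods (Poisson/negative
  binomial), or clustered standard errors: the analysis is plain OLS on
  logged counts.
* The percent-disrupted denominator defaults to predicted M0 services
  (configurable to observed); future-period denominators likewise come
  from M0 projections unless a births table is supplied.
* Scenario labels are opaque strings; nothing is downloaded, regridded or
  bias-corrected.
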