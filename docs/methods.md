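# Methods

## Damage model

Attributable mortality risk uses the log-linear concentration-response
form standard in regulatory health-impact assessment:
`M = γ(1 − e^{−βC})`, with γ the all-cause baseline mortality rate of the
person's age cohort in their county, β the pollutant's log-risk slope, and
C the county period-mean concentration. M is bounded by γ, saturates onto
it as C → ∞, and linearizes to γβC for small βC. Risk is assigned at the
person level from the cohort-county cell; income is attributed to persons
as total household income, and household damage is the sum of member
damages — the household is the unit of analysis (an `individual` switch
replicates each household row once per member instead).

β values are configuration, not constants. The shipped defaults are
derived from published relative risks via `β = ln(RR)/Δ`: PM2.5 RR 1.06
per 10 µg/m³ (Krewski et al., default) and 1.14 per 10 µg/m³ (LePeule et
al., sensitivity); O3 RR 1.0052 per 10 ppb (Bell et al.). Every run echoes
its β and VSL values in the result metadata.

The VSL is $10.2M (2011) by default, uniform across persons; sensitivities
use $3.3M uniform, or an income-varying VSL
`VSL_i = base·(I_i/Ī)^0.4` with the analysis-sample mean income as
reference. Households with non-positive income receive the base VSL, since
the power law is undefined there. Damage is linear in the VSL, so the
uniform scenarios are exact rescalings of each other's damage vectors. A
per-year VSL table is accepted in configuration for multi-year runs rather
than computing escalation from an income series.

Adjusted income is `I^a = I^m − D` and is allowed to be negative; negative
*market* incomes are also retained as-is. An optional county deflator hook
exists for cost-of-living adjustment but is off by default and untested
against any published procedure.

## Inequality statistics

The generalized covariance Gini `G = 2·Cov(Y/μ, F(Y))` admits negative
values while μ > 0; μ ≤ 0 is a hard error. Two numerical conventions are
load-bearing: F uses mid-ranks for ties, and the covariance divides by n.
Together they make the covariance form equal the pairwise form
`Σ|y_i−y_j|/(2n²μ)` exactly (to ~1e-12), which the suite checks against an
independent O(n²) oracle on random signed vectors. Useful identities the
tests exercise: scale invariance, the translation law
`G(Y−c) = G(Y)·μ/(μ−c)` (the mechanism by which deducting a
roughly-uniform damage inflates the Gini even before any regressivity),
and the lognormal closed form `G → 2Φ(σ/√2) − 1`.

Bootstrap SEs resample households with replacement (B = 200 by default,
deterministic given a seed); a resample with non-positive mean is redrawn,
capped at 10 attempts. For a lognormal(0,1) sample at n = 5000 the
bootstrap SE was checked against a direct Monte Carlo of the Gini's
sampling SD (~0.006 over 2000 independent samples).

Quintile shares sort ascending with stable tie order and split into five
contiguous, equally sized (unweighted) household groups; the bottom share
can be negative. The pollutant decomposition of damage inequality is the
Lerman–Yitzhaki covariance share `s_k = Cov(D_k, F(D))/Σ_m Cov(D_m, F(D))`,
chosen because it decomposes the damage *Gini*, sums to one by
construction, and reduces to the component factor when a component is
proportional to the total; plain level shares `ΣD_k/ΣD` are available via
`method="level"`. Group decompositions compute independent Ginis per race
or census division (no between/within decomposition is attempted); groups
with n < 2 or non-positive mean are skipped with a warning, and
median-ratio denominators with non-positive medians yield NaN with a
warning rather than an error.

## Data preparation

* Top-coding replaces incomes strictly above each state's 99.5th
  percentile with the mean of those incomes. The quantile is nearest-rank
  (type 1) — deterministic and simple; mean replacement preserves state
  income totals exactly.
* Mortality cells with fewer than 20 deaths are dropped (the reliability
  convention of county vital-statistics files); the filter is idempotent.
* Monitor readings are averaged unweighted to (county, pollutant). The O3
  exposure metric is taken as the annual mean of the period values, the
  same as PM2.5; readings are assumed pre-aggregated to the analysis year.
  Households in counties lacking either pollutant, or with any member in a
  censored mortality cell, are excluded (counts logged and reported in run
  metadata), not imputed.

County and state identifiers are opaque strings; no geographic semantics
are enforced. The analysis is unweighted throughout (no survey weights).

## Synthetic population

The generator emulates the statistical structure of the real inputs —
household survey extracts, county mortality files, and regulatory monitor
data — at desk scale: 20 states × 25 counties × 200 households (100k
households, 500 counties) by default, chosen to run the full pipeline in
seconds while leaving county-level statistics well resolved.

* Incomes are lognormal (median ≈ $50k, σ = 0.87) with race-level
  log-shifts and a county-level component (SD 0.22); the implied market
  Gini is ≈ 0.48 after top-coding. A small fraction (4e-4) of households
  draw negative market income.
* County PM2.5 (mean 10.2 µg/m³, SD 2.05) and O3 (mean 28 ppb, SD 4.5)
  load on the county-income z-score with standardized slope −0.55, so
  poorer counties are more polluted; 1–3 monitors per county and pollutant
  scatter around the county level (5% of the mean).
* Mortality is `rate_a · exp(−0.30·z(county income) + ε)`, ε ~ N(0, 0.12),
  over 15 age cohorts with non-decreasing base rates from 2e-4 (children)
  to 0.08 (75+); each cell draws a Poisson death count at a cell population
  of 100k, so ~8% of cells fall under the 20-death reliability cut.
* Households have 1–6 members with cohorts drawn iid from a roughly
  uniform age pyramid; race mixture ≈ US shares.

Defaults were calibrated by forward simulation so that person-level
exposure Ginis land near 0.11 (PM2.5) / 0.09 (O3) and the baseline-risk
Gini near 0.7–0.76 — the regime in which exposure is distributed fairly
equally but risk is not, which is what makes the damage deduction
regressive.

What the generator does **not** emulate: age–income correlation (elderly
households draw from the same income distribution as everyone else, so the
share of households with negative adjusted income, ~16%, is higher than in
real microdata where retirement income cushions the high-mortality
cohorts); race-specific exposure conditional on county; spatial
autocorrelation and explicit geography; temporal dependence (years are
generated independently). Passing tests therefore demonstrate the
correctness and qualitative behaviour of the accounting chain — not
quantitative agreement of adjusted-income inequality levels with any real
population.

## Numerical notes and limitations

* `1 − e^{−βC}` is computed with `expm1`; for βC ≳ 37 the float saturates
  onto γ, so the strict bound M < γ holds only below that (irrelevant for
  ambient ranges, where βC < 0.2).
* Mortality rates are clipped to [1e-6, 0.999] after the income
  multiplier.
* Gini requires μ > 0: a population whose mean adjusted income is negative
  (possible under the steep-slope scenario on a poor subgroup) cannot be
  summarized by this statistic; group decompositions skip such groups with
  a warning.
* Bootstrap resampling is at the household level only; no clustering by
  county, so SEs understate sampling error under county-level shocks.
* The sensitivity grid covers the slope and VSL choices, not alternative
  exposure metrics or cohort structures.
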