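# airineq — inequality of pollution-adjusted household income

Market income understates inequality when the costs of breathing polluted
air are ignored: poorer counties are both more polluted and have higher
baseline mortality, so the mortality burden of ambient PM2.5 and ozone
falls disproportionately on households least able to bear it. `airineq`
implements the full accounting chain for this question: it attributes a
share of each person's baseline mortality risk to pollutant exposure,
monetizes that risk, deducts the resulting damage from household market
income, and measures inequality of the adjusted income — which can be
negative for the poorest households — with a generalized Gini coefficient.

It is intended for environmental and health economists studying the
distributional incidence of air pollution. Because the microdata this kind
of analysis uses (census household extracts, county mortality files,
regulatory monitor readings) are restricted or bulky, the package includes
a synthetic-population generator that reproduces their statistical
structure, so the entire pipeline is runnable and testable from a clean
checkout.

## The model

For a person in age cohort *a*, county *r*, the mortality risk attributable
to pollutant *p* under a log-linear concentration-response function is

    M_p = γ_{a,r} · (1 − e^{−β_p C_{p,r}})

where γ is the cohort-county all-cause baseline mortality rate, β_p the
per-unit log-risk slope from the epidemiological literature (defaults:
Krewski et al. for PM2.5, RR 1.06 per 10 µg/m³; Bell et al. for O3,
RR 1.0052 per 10 ppb; LePeule et al., RR 1.14 per 10 µg/m³, as a
sensitivity), and C the county's period-mean ambient concentration.
Monetized household damage sums over members and pollutants,

    D = Σ_members Σ_p VSL · M_p ,

with a value of a statistical life of $10.2M (sensitivities: $3.3M, and a
VSL scaled by household income with elasticity 0.4). Adjusted income is
I^a = I^m − D.

Inequality is measured with the generalized covariance-based Gini

    G(Y) = 2 · Cov(Y/μ(Y), F(Y)) ,

valid for vectors with negative entries as long as the mean is positive
(G may then exceed 1). With mid-rank ties and a 1/n covariance this equals
the pairwise form Σ_ij |y_i − y_j| / (2 n² μ) exactly, which the test suite
verifies against an independent O(n²) oracle. Bootstrap standard errors,
quintile income shares, a Lerman–Yitzhaki decomposition of damage
inequality by pollutant, per-group Ginis, and median-income ratios round
out the statistics.

Before damages are computed, three preparation rules are applied to the
inputs: incomes above each state's 99.5th percentile are replaced by the
mean of those incomes (top-coding), mortality cells with fewer than 20
deaths are dropped as unreliable, and monitor readings are averaged to
county level; households in counties without both pollutants monitored are
excluded.

## Worked example

```sh
python analysis/01_simulate.py    # 100k households, 500 counties, seed 42
python analysis/02_prepare.py
python analysis/03_damages.py
python analysis/04_inequality.py
python analysis/05_sensitivity.py
```

On the default synthetic population the chain prints:

```
analysis sample: 83749 households (excluded 16251 with censored mortality cells, ...)
mean market income : $      66,266
mean damage        : $      19,287 (PM2.5 $15,429, O3 $3,858)
households with negative adjusted income: 16.3%
Gini market_income    0.483 (0.001)
Gini externality      0.687 (0.001)
Gini adjusted_income  0.809 (0.004)
share PM2.5 0.802 | share O3 0.198 | ratio adjusted/market 1.674
market quintile shares: +0.039  +0.082  +0.132  +0.217  +0.530
adjusted quintile shares: -0.136  +0.058  +0.134  +0.253  +0.692
```

Read: market income alone has a Gini of 0.483; pollution damage is more
concentrated than income (Gini 0.687) and anti-correlated with it, so
deducting it raises the Gini to 0.809 (bootstrap SEs in parentheses).
The bottom quintile's share of adjusted income is *negative* (−13.6%) while
the top quintile's share rises from 53% to 69% — the damage deduction acts
like a regressive tax concentrated on the poorest fifth. About 80% of
damage inequality stems from PM2.5. The sensitivity grid preserves the
ordering: a $3.3M VSL tempers the adjusted Gini to 0.551 (still above the
market 0.483), the steeper PM2.5 slope pushes it past 1, and the
income-varying VSL lands in between.

The same chain is available as a CLI (`airineq simulate|prepare|damages|
inequality|report|all`), e.g. `airineq all --seed 42 --out-dir results/`.

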