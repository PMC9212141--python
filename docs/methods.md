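# Methods

## Model

For indicator level `y_it` of country `i` at time `t`:

```
ln(y_it) = α + β₁ ln(GDPpc_it) + β₂ health_it + β₃ gini_it + β₄ D_i + f_it + ε_it
```

- `GDPpc`: GDP per capita in constant-price currency units; the summary
  development variable. The log-log form makes `β₁` an elasticity.
- `health`: public health expenditure, % of GDP (proxy for service
  availability); `gini`: Gini index on the 0–100 scale (proxy for access).
  Both enter untransformed.
- `D`: WHO-region dummies (AFR, AMR, EMR, EUR, SEAR, WPR), AFR as the
  reference; included to absorb geographic non-linearities in the
  income–health relationship.
- `f_it`: country and period fixed effects (panel regime only); `ε_it`:
  idiosyncratic error.

The curve is interpreted as an *average global* relationship: pooled across
countries it serves as a counterfactual benchmark, not a causal model of any
single country.

## Estimation

**Regime choice.** An indicator is fitted as a panel when it is flagged
`panel_eligible` in the registry (a long, multi-period series) *and* at
least two period bins are populated in the data at hand; otherwise a single
cross-section is used (the latest populated period per country). The flag is
carried in the registry CSV and fully overridable.

**Period averaging.** Panel fits use period averages to raise degrees of
freedom and damp serial correlation. Bins are calendar-anchored at 2000 with
width 5 ([2000–2004], [2005–2009], …; earlier bins analogously); a bin
exists whenever it contains at least one observation, and covariates are
averaged over the same bins. Width 1 reduces to annual data.

**Panel regime.** The two-way fixed-effects estimator demeans the response
and regressors by country and adds period indicator terms (earliest period
as reference); this is numerically identical to least squares with explicit
country and period dummies (verified against that oracle to 1e-8).
Time-invariant regressors — the region dummies — are annihilated by the
within transform: any column whose demeaned norm falls below
`1e-10 × max(1, original norm)` is dropped and recorded. Remaining
collinearity is resolved by a greedy rank scan in declared column order
(Gram–Schmidt residual norm below `1e-8` relative), so ties always drop the
later column — a deterministic rule. The coefficient covariance is clustered
by country with the CR1 small-sample factor `G/(G−1) × (n−1)/(n−G−k)`;
p-values use a t distribution with `G−1` degrees of freedom. The reported R²
is the within R²; `rmse = sqrt(SSR/(n−G−k))`; the F statistic is the within
regression F over all retained regressors. The constant is chosen so the
estimated country effects average to zero, which makes the counterfactual
(below) well defined. `corr_fe` is reported as the correlation between the
estimated country effects and the fitted country-mean linear predictor — one
plausible reading of a panel-only association diagnostic whose published
definition is not stated; it feeds no downstream decision.

**Cross-section regime.** OLS with intercept and retained region dummies;
empty (all-zero) dummy columns are dropped and recorded. Standard errors are
HC1; p-values use t with `n−k` degrees of freedom; F is the classical
overall regression F. Under homoskedastic noise HC1 and classical errors
agree within a few percent at moderate n (checked by simulation).

**Missing data.** Rows with any missing field, or with a non-positive
indicator value or GDPpc, are deleted listwise before logs, with the count
logged. No offsets are added: offsets distort elasticities.

**Significance gate.** An indicator is projectable when `p(β₁) < α`
(strict, default α = 0.05). The bundled transcription of the published
coefficient table encodes its significance markers as representative
p-value bounds (``***``→1e-4, ``**``→5e-3, ``*``→2.5e-2, unstarred→0.5), so
the same gate logic applies to printed and freshly fitted curves; on the
bundled table exactly 32 of 38 series pass.

## Gap index

`observed` is the arithmetic mean of a country's post-2015 observations
(window configurable). `expected` is the curve prediction at the country's
window-averaged covariates (a config switch selects latest-year covariates
instead), *excluding* the country's own fixed effect — including it would
force every gap to zero by construction. For panel fits the period effect of
the most recent estimated period enters (configurable to the average
effect); the published choice is not stated, and the latest period matches
the post-2015 window. The gap is

```
gap = direction × (observed − expected) / expected
```

with `direction = +1` (higher is better) or `−1` (lower is better), so
positive gaps always mean better than expected. Reporting bands are
`gap ≥ +0.1` better, `|gap| < 0.1` as expected, `gap ≤ −0.1` worse
(configurable; the published color scale is not numerically specified).
Indicators failing the significance gate are omitted from the scorecard.

Note an identification limit: under country fixed effects, regional
coefficients are not separable from country effects, so whatever regional
structure the data has is absorbed into the estimated country effects and
therefore *shows up in the gaps*. The "all gaps vanish for on-curve
countries" property holds exactly when the data-generating process has no
country-specific structure of any kind (no country effects, no regional
coefficients, no noise).

## Projections

Cumulative decade growth is `G = Π(1+g_t) − 1` over annual rates,
equivalently the endpoint ratio `GDPpc_2030/GDPpc_2019 − 1` — the two agree
whenever the inputs are consistent, and the endpoint ratio is what the
bundled scenario table encodes. Holding Gini and health expenditure constant
over the decade, all non-GDP terms cancel between baseline and horizon, so

```
projected = baseline × (1 + G)^β₁
```

The baseline is the same post-2015 average used by the gap stage (a config
switch selects the latest observation), keeping the two stages jointly
interpretable. Growth applies as one cumulative factor; annual paths are
derivable but not emitted. The direction-adjusted gain
`direction × (projected − baseline)/baseline` is positive exactly when
`direction × β₁ > 0` under positive growth: a mortality-type indicator
(direction −1) with a negative elasticity improves with growth, while e.g. an
alcohol-consumption-type indicator (direction −1, positive elasticity)
worsens. No uncertainty intervals are produced for projections.

## Theme and subregion aggregation

Per country and theme, `progress = Σ adjusted_gain / n_theme`, where the sum
runs over the theme's *projected* indicators but the divisor is the theme's
full registry size — a missing indicator reduces measured progress
proportionally rather than being averaged away (a divisor by available count
would not). Subregional summaries are unweighted means over member
countries; the bundled membership table encodes the four American subregions
with Mexico excluded from the North America mean and Guyana (an extreme
growth outlier) from the South America mean, both overridable. Pipeline runs
on synthetic data group countries by WHO region instead (config
`subregion_source`).

## Registry encoding

Directions follow each indicator's plain meaning: mortality, incidence,
malnutrition (including childhood overweight), substance use, violence,
pollution and PM2.5 carry −1; coverage, personnel density, IHR capacity and
data completeness carry +1 (23 negative, 15 positive). `panel_eligible` is
true for the MDG-era series with harmonized multi-period histories (15
indicators); ambiguous cases default to the cross-sectional regime. Every
entry is overridable via a registry CSV with the same schema.

## Synthetic data

The generator draws from the structural model above with known parameters:
log GDPpc follows a per-country random walk with drift (0.02/yr, volatility
0.03/√yr, initial ln GDPpc ~ N(8.0, 1.2²)) so the within estimator is
identified; Gini and health expenditure wander inside realistic bands
(28–55 and 2–10, clipped); regions are assigned round-robin so every dummy
is estimable in cross-sections; covariates are constant within a period bin
and one observation is emitted per bin by default (several per bin on
request, sharing the bin's covariates). Defaults describe a mortality-like
indicator: elasticity −1.05, health and Gini coefficients −0.03 and 0.01,
regional coefficients within ±0.3, country-effect SD 0.3, period-effect SD
0.05, noise SD 0.1, 60 countries over six 5-year periods (1990–2019) —
magnitudes consistent with the published coefficient and fit-statistic
ranges. One seeded generator stream determines everything.

The generator reproduces only this structural model. It does not mimic the
marginal distributions, measurement error, reporting gaps or cross-indicator
correlations of real WHO series, so passing tests demonstrate correctness of
the estimators and pipeline arithmetic, not forecast accuracy on real data.

**Test problem sizes.** The Monte-Carlo suites use 60 countries × 6 periods
with 200–300 replicates for recovery/coverage (observed: |bias| ≈ 0.002,
coverage ≈ 0.96), 25 countries × 100 replicates per noise level for RMSE
monotonicity, and 50 random 4–8 country panels for the dummy-variable
equivalence oracle; these sizes give stable Monte-Carlo estimates while
keeping the suite fast.

## Known limitations

- Published coefficient values and theme-progress cells are not
  reproducible from first principles here: they require the original
  WHO/World Bank/IMF extracts and unstated per-country indicator
  availability. The bundled transcription carries the printed values for
  gating and projection arithmetic only.
- No spline/segmented curves, likelihood-ratio non-linearity tests or
  dynamic-panel (lagged endogenous, GMM) estimators: the final specification
  is the static model above.
- The cross-section regime uses one (latest) record per country; pooling
  multiple periods without fixed effects is deliberately not offered.
- Scorecard rendering is CSV classification only; no heat-map graphics.
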