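# immunocost

Bayesian meta-regression of routine immunization **delivery cost per dose**
(the non-vaccine cost of administering one dose through fixed-facility
childhood services), for health economists and immunization program analysts
who need standardized country-year unit costs where empirical costing
studies are missing, old, or heterogeneously reported.

## The model

Costing studies report cost per dose covering different subsets of four
delivery cost categories — labor, supply chain, other service delivery, and
capital — some as a single total, some disaggregated by category. The model
synthesizes all of them at once. Each category *l* has its own log-scale
intercept with slopes shared across categories:

```
ĉᵢˡ = exp(β₀ₗ + β₁·Yearᵢ + β₂·Econᵢ + β₃·Singleᵢ
          + β₄·log(Doses)ᵢ + β₅·DTP3ᵢ + β₆·log(GDP)ᵢ + β₇·log(Pop)ᵢ)
```

An observation's expected value is the sum of the categories it covers,
`tcᵢ = Σₗ Iᵢₗ · ĉᵢˡ`, and the observed cost is Gamma distributed with
shape α and rate α/tcᵢ (mean tcᵢ, variance tcᵢ²/α — noise scales with the
expected cost). Continuous predictors (Year, log Doses, log GDP, DTP3,
log Pop) are standardized on the analysis sample; `Econ` (financial 0 /
economic 1 / undefined 2) and `Single` (programmatic 0 / single-antigen 1)
enter as coded. Priors are N(0, 1) on all coefficients and half-Cauchy(5)
on α; posterior sampling uses four chains of 5000 adaptive-Metropolis
iterations with the first 2500 discarded (10,000 retained draws), with
split-R̂ convergence diagnostics.

The fitted model turns into: country-year **predictions** (programmatic,
economic or financial, all categories, converted to 2018 USD via
country CPI and market exchange rates, population-weighted aggregates), and
**first differences** — the posterior percent change in cost per dose for a
unit change in one predictor, e.g. `100·(exp(β₅·0.01/sd) − 1)` per
percentage point of DTP3 coverage, which is baseline-free under the log
link.

## Worked example

```python
import immunocost as ic

# a synthetic evidence base: 29 studies, ~50 estimates, category-subset
# reporting, Gamma cost noise around known parameters
sim = ic.simulate_dataset(ic.ScenarioSpec(seed=1))

model = ic.GammaCostMetaRegression(seed=2)       # 4 chains x 5000, N(0,1) priors
model.fit(sim.analysis_frame, sim.y)
print(model.draws_.summary().loc[["beta_dtp3", "beta_log_pop", "alpha"]].round(3))
```

```
               mean     sd   lo95  median   hi95
beta_dtp3     0.352  0.108  0.135   0.352  0.581
beta_log_pop -0.331  0.126 -0.593  -0.324 -0.101
alpha         1.156  0.161  0.876   1.144  1.496
```

Here DTP3 coverage raises and population lowers the expected cost per dose
(posterior 95% intervals exclude zero), and α ≈ 1.2 means residual noise on
the order of the prediction itself — both patterns the generator built in
(true values 0.29, −0.30, 1.08). First differences translate coefficients
onto the cost scale:

```python
print(ic.standard_first_differences(model.draws_, model.standardizer_,
                                    model.mean_doses_).round(2))
```

```
   predictor         delta_description  mean_pct  lo95_pct  hi95_pct
0       year          +1 calendar year     -2.88     -7.97      1.82
1  log_doses       +1 dose in schedule      1.07     -6.43      7.98
2    log_gdp         GDP per capita x2     12.45    -18.60     50.35
3    log_pop             population x2    -10.24    -17.73     -3.27
4       dtp3  +1 percentage point DTP3      4.19      1.58      7.01
```

i.e. a population doubling is associated with a ~10% lower cost per dose, a
percentage point of DTP3 with ~4% higher. The same model object feeds
`prediction_table` / `weighted_aggregate` for country-year tables in 2018
USD, and the `immunocost` CLI (`simulate` / `fit` / `predict` / `effects` /
`report`) runs the whole pipeline from CSVs to a manifest, including the
sensitivity variants (`--prior weak|noninformative`, `--exclude-outliers`
for sub-$0.01 observations).

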