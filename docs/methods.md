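# Methods

## Model

One observation is a cost-per-dose estimate `y_i > 0` from a costing study,
tagged with the delivery cost categories it covers (labor, supply chain,
other service delivery, capital), its cost type (financial, economic, or
undefined), its scope (full programmatic schedule vs. the incremental cost
of a single newly introduced antigen), and the country-year it was measured
in. Studies report category subsets inconsistently — some only a total, some
per-category rows — and the model is built to absorb exactly that
heterogeneity.

Each category gets its own intercept on the log scale; the seven slopes
(study year, cost-type code, single-antigen indicator, log schedule size,
DTP3 coverage, log GDP per capita, log population) are shared across
categories. The expected value of an observation is the sum of the expected
category costs it includes, and the likelihood is Gamma with shape `α` and
rate `α / tc_i`:

* mean `tc_i`, variance `tc_i² / α` — the residual spread scales with the
  prediction, which is the right behaviour for strictly positive costs
  spanning two orders of magnitude;
* `α` is shared across observations and absorbs both sampling noise and
  methodological heterogeneity between studies. Values near 1 (an
  exponential-like noise law) indicate residual uncertainty comparable to
  the prediction itself, which is what fits of realistic portfolios give.

Assumptions worth stating plainly: no study-level random effects (every row
is conditionally independent given covariates), category costs combine
additively, covariate effects are common to all categories, and the
log-linear form means effects are multiplicative.

### Priors and sensitivity variants

Coefficients (intercepts included) get independent N(0, sd) priors with
sd = 1 by default. The shape gets half-Cauchy(scale 5); a Cauchy has no
finite standard deviation, so "spread 5" is implemented as the scale
parameter. Variants:

* `weak` — coefficient sd 10;
* `noninformative` — improper flat priors on coefficients, half-Cauchy kept
  on `α` so the posterior stays proper.

A third sensitivity re-specification drops observations below $0.01 per
dose (`exclude_outliers`), a data variant rather than a prior variant.

### Coding decisions

* `Econ` enters as one numeric covariate coded financial = 0, economic = 1,
  undefined = 2, matching the single-slope form of the category equations,
  even though the coding is really ordinal; `econ_coding="dummy"` expands it
  into two indicators for users who prefer that, but it is not the default.
* Natural logs everywhere; after standardization the base is irrelevant to
  the fit, and natural-log deltas (`ln 2` for a doubling) keep first
  differences exact.
* DTP3 is a proportion in [0, 1]; "one percentage point" is Δ = 0.01.
* Continuous predictors are z-scored with moments from the fitted sample
  only. Prediction covariates — including years outside the fitted range —
  reuse those moments; extrapolation warns but never errors.
* When an estimate has both a total row and category rows, the total is
  redundant and dropped (the category rows are the higher-granularity
  data). Estimate identity is the `(study, cost type, scope, base year)`
  tuple unless an explicit `estimate_id` column is present.
* Routine-schedule dose counts missing for a study year fall back to the
  most recent prior year, unbounded backwards, warning when the gap exceeds
  3 years.

## Sampling

The posterior is sampled with a self-contained adaptive random-walk
Metropolis sampler:

1. the mode is found by L-BFGS with the analytic gradient (the shape is
   sampled as `log α`, with the Jacobian term included);
2. the proposal covariance is the inverse negative Hessian at the mode
   (finite differences of the analytic gradient, eigenvalue-clipped at
   1e-8 to stay positive definite);
3. during burn-in the global proposal scale follows a Robbins–Monro
   recursion toward 0.234 acceptance, and halfway through burn-in the
   covariance is refreshed from the accumulated draws; adaptation freezes
   at the end of burn-in so retained draws come from a fixed kernel;
4. chains are seeded by `SeedSequence.spawn`, making runs exactly
   reproducible per seed, and started from mode + 0.1·sd jitter.

The default configuration mirrors the analysis this model was designed for:
4 chains × 5000 iterations, first 2500 discarded, 10,000 retained draws.
Split-R̂ (each chain halved, classic between/within variance ratio) is
computed for every parameter; the warning threshold is 1.01, deliberately
strict for a random-walk sampler, and a warning never rejects a run —
typical fits at the default length sit at max R̂ ≈ 1.02–1.06, which is
adequate for posterior means and 95% quantiles given 10,000 retained draws.
Identical constant chains yield R̂ = NaN with a warning; a single chain is
an error. The sampler core is generic (any log-density callable), which is
what the grid-quadrature equivalence test exercises on a two-parameter
restriction of the model.

Uncertainty intervals everywhere are equal-tailed 2.5/97.5 posterior
quantiles of the *deterministic* prediction `tc` — parameter uncertainty
only, not Gamma posterior-predictive intervals, which with `α ≈ 1` would be
several times wider. This is the reading consistent with the interval
widths such analyses report; it is a genuine modelling choice, documented
here rather than hidden.

## Predictions, currency, aggregation

Country-year predictions fix `Single = 0` (programmatic), all four
categories included, `Econ` = 1 (economic) or 0 (financial). Totals are
composed draw-wise — summed within a draw, then summarized — so the total
mean equals the sum of category means exactly, and economic/financial
predictions differ only through `β₂`, making their ratio constant across
categories within a draw.

Model-scale prices carry the data's price year (2016 USD by convention);
conversion to 2018 USD goes through local currency: multiply by the
source-year exchange rate, inflate by the country CPI ratio, divide by the
target-year rate. The factor is multiplicative, so conversion commutes with
aggregation under a common factor. Aggregates are population-weighted
per-draw means across countries (weights from the prediction year,
normalized within group), summarized afterwards; groups are global, WHO
region, or World Bank income level from a versioned lookup CSV.

First differences report `100·(exp(β_k · Δ/sd_k) − 1)` summarized over
draws — the posterior mean of the transformed quantity, not the transform of
the posterior mean (Jensen's gap between the two is small but real). Under
the log link this is exactly the two-prediction ratio at any baseline, which
the tests verify to 1e-12 per draw. The "+1 dose" change is evaluated at the
sample-mean schedule size m as Δ = ln((m+1)/m) on the log scale, since an
absolute dose change is not baseline-free for a logged covariate.

## Synthetic data

The generator reproduces the statistical structure of the real evidence
base: ~29 studies, each with one or two estimates (two means an
economic/financial pair), ~35% of estimates disaggregated into category
rows (occasionally with duplicate category rows standing in for multi-site
reporting), category-inclusion probabilities of (0.92, 0.98, 0.63, 0.63),
single-antigen share 28/52, cost-type mix (27, 11, 14)/52, base years
2001–2017. Covariates are drawn around the observed-sample moments — doses
12 (3), GDP per capita lognormal matched to $1550 ($1300), DTP3 0.88 (0.09)
truncated to [0, 1], population lognormal matched to 5.71e7 (2.07e8); the
lognormal families are a choice, made because the printed standard
deviations exceed or approach the means, which rules out anything
thin-tailed. Countries carry mild persistent GDP/population growth and DTP3
drift across the panel years. Costs are drawn from the model's own noise
law, `y ~ Gamma(α, α/tc)`, with `tc` computed from the true parameters.

Two details matter for interpreting tests built on this generator. First,
the true parameters are defined on the standardized scale of the *realized*
analysis sample, so a pipeline fit targets exactly the recorded truth with
no standardization mismatch. Second, covariates are independent across
countries by default, studies are conditionally independent given
covariates, and category-inclusion is independent of cost level — real
portfolios violate all three (e.g. financial estimates under-report
capital), so passing recovery tests demonstrates correctness of the
machinery under the model's own assumptions, not robustness to real-world
reporting biases.

Pathology switches (zero-cost rows, sub-$0.01 outliers, outreach-only rows,
missing-covariate rows) exist solely to exercise validation and filter
paths and are off by default.

## Problem sizes and numerical choices

Tests and the acceptance script scale runs to what the checks need: the
grid-quadrature oracle uses a 60-observation two-parameter restriction on a
501² grid; parameter-recovery uses 20 replicate portfolios of ~500 analysis
rows fitted with 4 × 1500 iterations (750 burn-in), enough for stable 95%
interval endpoints; full-default fits (4 × 5000) are used for the worked
example and the acceptance script's main run. Quantiles are linear
interpolation (numpy default). Degenerate inputs fail loudly: non-positive
costs, empty post-filter datasets, zero-variance standardization columns,
all-excluded categories, and missing covariate or currency entries all
raise named errors.

## Known limitations

* No study random effects: repeated estimates from one study are treated as
  independent, understating uncertainty when studies cluster.
* The shared-slope assumption forces every covariate to act identically on
  all four categories.
* The adaptive Metropolis sampler needs ~10× more iterations than a
  gradient-based sampler would for the same effective sample size; the
  defaults account for that, but very large datasets would benefit from a
  gradient backend plugged into the same generic chain runner.
* Predictions for covariate combinations far outside the fitted sample
  (rich, small, low-coverage countries) inherit the extrapolation risk any
  regression has; the extrapolation warning flags years, but covariate-space
  extrapolation is not flagged.
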