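"""Synthetic costing-study portfolios and country fixture tables.

The generator emulates the structure of the evidence base the meta-regression
was built for: a few dozen costing studies in low- and middle-income
countries, each contributing one or two cost-per-dose estimates (a study may
report both an economic and a financial figure), with roughly a third of
estimates disaggregated into per-category rows and the rest reported only as
totals with a known category-inclusion pattern.  Covariates are drawn around
the observed-sample moments: schedule size ~ 12 (3) doses, GDP per capita
~ $1550 ($1300, lognormal), DTP3 coverage ~ 0.88 (0.09, truncated to [0,1]),
population ~ 5.71e7 (2.07e8, lognormal — the heavy tail matches an sd far
above the mean), base years 2001-2017.

Observed costs follow the model's own noise law: y ~ Gamma(alpha, alpha/tc)
with tc composed from the true category cost equations.  The true parameters
are defined on the standardized scale of the realized analysis sample, so a
pipeline fit of the generated data targets exactly the recorded truth.

What this generator does not emulate: within-study site-level sampling,
correlated covariates (independent by default; pass ``covariate_corr``),
and reporting-quality heterogeneity beyond the explicit pathology switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CONTINUOUS_COLUMNS
from .likelihood import CATEGORIES, ModelParams, total_cost_matrix

WHO_REGIONS = (
    "Africa",
    "Americas",
    "Eastern Mediterranean",
    "Europe",
    "Southeast Asia",
    "Western Pacific",
)
INCOME_LEVELS = ("low", "lower_middle", "upper_middle")


def table_params() -> ModelParams:
    """Reference parameter point used as the generator's default truth:
    category intercepts near (0.08, -0.97, -0.07, -1.16), slopes near
    (-0.14, -0.06, -0.49, 0.01, 0.29, 0.19, -0.30), shape 1.08."""
    return ModelParams(
        intercept_labor=0.08,
        intercept_supply_chain=-0.97,
        intercept_service_delivery=-0.07,
        intercept_capital=-1.16,
        beta_year=-0.14,
        beta_econ=-0.06,
        beta_single=-0.49,
        beta_log_doses=0.01,
        beta_dtp3=0.29,
        beta_log_gdp=0.19,
        beta_log_pop=-0.30,
        alpha=1.08,
    )


@dataclass
class ScenarioSpec:
    """Generating conditions for one synthetic portfolio."""

    params: ModelParams = field(default_factory=table_params)
    n_studies: int = 29
    n_countries: int = 24
    p_second_estimate: float = 23 / 29      # E[estimates] ~ 52 from 29 studies
    p_disaggregate: float = 18 / 52
    category_probs: tuple[float, float, float, float] = (0.92, 0.98, 0.63, 0.63)
    cost_type_probs: tuple[float, float, float] = (27 / 52, 11 / 52, 14 / 52)
    p_single_antigen: float = 28 / 52
    p_duplicate_category_row: float = 0.15  # multi-site style repeat of one category
    emit_redundant_totals: bool = True
    doses_mean: float = 12.0
    doses_sd: float = 3.0
    gdp_mean: float = 1550.0
    gdp_sd: float = 1300.0
    dtp3_mean: float = 0.88
    dtp3_sd: float = 0.09
    pop_mean: float = 5.71e7
    pop_sd: float = 2.07e8
    year_min: int = 2001
    year_max: int = 2017
    price_year: int = 2016
    # pathology switches (all off by default) to exercise error paths
    n_zero_cost_rows: int = 0
    n_subcent_outliers: int = 0
    n_outreach_rows: int = 0
    n_missing_covariate_rows: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_second_estimate",
            "p_disaggregate",
            "p_single_antigen",
            "p_duplicate_category_row",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(not 0 <= p <= 1 for p in self.category_probs):
            raise ValueError("category_probs must be probabilities")
        if abs(sum(self.cost_type_probs) - 1) > 1e-9:
            raise ValueError("cost_type_probs must sum to 1")
        for name in ("doses_mean", "doses_sd", "gdp_mean", "gdp_sd", "dtp3_sd",
                     "pop_mean", "pop_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedData:
    """Generated portfolio: raw CSV-schema tables plus the generating truth."""

    observations: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict
    analysis_frame: pd.DataFrame   # the rows a clean pipeline run would fit
    y: np.ndarray
    tc: np.ndarray                 # generating expected cost per analysis row


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def _country_codes(n: int) -> list[str]:
    return [f"C{i:02d}" for i in range(n)]


def _country_panel(
    rng: np.random.Generator, spec: ScenarioSpec, end_year: int = 2018
) -> pd.DataFrame:
    """Country-year covariate panel with mild, persistent within-country
    trends (GDP/population growth, slow DTP3 drift, occasional schedule
    additions)."""
    years = np.arange(spec.year_min, end_year + 1)
    gdp_mu, gdp_sigma = _lognormal_params(spec.gdp_mean, spec.gdp_sd)
    pop_mu, pop_sigma = _lognormal_params(spec.pop_mean, spec.pop_sd)
    rows = []
    for code in _country_codes(spec.n_countries):
        doses = max(1, int(round(rng.normal(spec.doses_mean, spec.doses_sd))))
        gdp = float(np.exp(rng.normal(gdp_mu, gdp_sigma)))
        pop = float(np.exp(rng.normal(pop_mu, pop_sigma)))
        dtp3 = float(np.clip(rng.normal(spec.dtp3_mean, spec.dtp3_sd), 0.2, 0.999))
        g_gdp = rng.normal(0.02, 0.02)
        g_pop = rng.normal(0.015, 0.005)
        for year in years:
            rows.append((code, int(year), doses, gdp, dtp3, pop))
            if rng.uniform() < 0.08:
                doses += 1
            gdp *= float(np.exp(g_gdp + rng.normal(0, 0.01)))
            pop *= float(np.exp(g_pop))
            dtp3 = float(np.clip(dtp3 + rng.normal(0, 0.01), 0.2, 0.999))
    return pd.DataFrame(
        rows, columns=["country_iso3", "year", "doses", "gdp_pc_usd", "dtp3", "population"]
    )


def simulate_dataset(spec: ScenarioSpec) -> SimulatedData:
    """Draw one portfolio under ``spec``.

    Returns the observations/covariates tables in the ingestion schema, the
    analysis rows a clean pipeline run would retain (totals for total-only
    estimates, category rows for disaggregated ones), the Gamma-noised
    costs, and a truth record holding the generating parameters and the
    standardization moments they refer to.
    """
    rng = np.random.default_rng(spec.seed)
    covariates = _country_panel(rng, spec)
    cov_idx = covariates.set_index(["country_iso3", "year"])
    countries = _country_codes(spec.n_countries)

    # --- draw the portfolio structure -----------------------------------
    estimates = []  # one dict per estimate
    for s in range(spec.n_studies):
        study_id = f"study{s:03d}"
        country = countries[rng.integers(0, spec.n_countries)]
        base_year = int(rng.integers(spec.year_min, spec.year_max + 1))
        if rng.uniform() < spec.p_second_estimate:
            cost_types = ["economic", "financial"]
        else:
            cost_types = [
                ["economic", "financial", "undefined"][
                    rng.choice(3, p=spec.cost_type_probs)
                ]
            ]
        for ct in cost_types:
            scope = "single_antigen" if rng.uniform() < spec.p_single_antigen else "programmatic"
            cats = [
                c
                for c, p in zip(CATEGORIES, spec.category_probs)
                if rng.uniform() < p
            ]
            if not cats:
                cats = ["labor"]
            disagg = rng.uniform() < spec.p_disaggregate
            cat_rows: list[str] = []
            if disagg:
                for c in cats:
                    cat_rows.append(c)
                    if rng.uniform() < spec.p_duplicate_category_row:
                        cat_rows.append(c)  # second site reporting the same category
            estimates.append(
                {
                    "study_id": study_id,
                    "estimate_id": f"{study_id}|{ct}|{scope}|{base_year}",
                    "country": country,
                    "base_year": base_year,
                    "cost_type": ct,
                    "scope": scope,
                    "categories": cats,
                    "cat_rows": cat_rows,
                    "disaggregated": disagg,
                }
            )

    # --- analysis rows (the rows the model will see) --------------------
    rows = []
    for est in estimates:
        cov = cov_idx.loc[(est["country"], est["base_year"])]
        base = {
            "study_id": est["study_id"],
            "estimate_id": est["estimate_id"],
            "country": est["country"],
            "year": float(est["base_year"]),
            "doses": float(cov["doses"]),
            "gdp_pc": float(cov["gdp_pc_usd"]),
            "dtp3": float(cov["dtp3"]),
            "pop": float(cov["population"]),
            "econ": float({"financial": 0, "economic": 1, "undefined": 2}[est["cost_type"]]),
            "single": float(est["scope"] == "single_antigen"),
        }
        if est["disaggregated"]:
            for c in est["cat_rows"]:
                row = dict(base)
                for cat in CATEGORIES:
                    row[f"inc_{cat}"] = int(cat == c)
                row["granularity"] = "category_row"
                row["category"] = c
                rows.append(row)
        else:
            row = dict(base)
            for cat in CATEGORIES:
                row[f"inc_{cat}"] = int(cat in est["categories"])
            row["granularity"] = "total"
            row["category"] = "NA"
            rows.append(row)
    frame = pd.DataFrame(rows)

    # --- standardize on the realized sample, compute tc, draw y ---------
    work = frame.copy()
    work["log_doses"] = np.log(work["doses"])
    work["log_gdp"] = np.log(work["gdp_pc"])
    work["log_pop"] = np.log(work["pop"])
    means = work[list(CONTINUOUS_COLUMNS)].mean()
    sds = work[list(CONTINUOUS_COLUMNS)].std(ddof=0)
    for c in CONTINUOUS_COLUMNS:
        work[c] = (work[c] - means[c]) / sds[c]
    X = work[["year", "econ", "single", "log_doses", "dtp3", "log_gdp", "log_pop"]].to_numpy()
    I = frame[[f"inc_{c}" for c in CATEGORIES]].to_numpy(dtype=float)
    tc = total_cost_matrix(spec.params.intercepts(), spec.params.slopes(), X, I)
    y = rng.gamma(shape=spec.params.alpha, scale=tc / spec.params.alpha)
    frame["tc_true"] = tc

    # --- observation table in the ingestion schema ----------------------
    obs_rows = []
    price = spec.price_year
    for i, (_, row) in enumerate(frame.iterrows()):
        obs_rows.append(
            {
                "study_id": row["study_id"],
                "country_iso3": row["country"],
                "base_year": int(row["year"]),
                "value_usd": float(y[i]),
                "price_year": price,
                "inc_labor": int(row["inc_labor"]),
                "inc_supply_chain": int(row["inc_supply_chain"]),
                "inc_service_delivery": int(row["inc_service_delivery"]),
                "inc_capital": int(row["inc_capital"]),
                "cost_type": ["financial", "economic", "undefined"][int(row["econ"])],
                "scope": "single_antigen" if row["single"] else "programmatic",
                "granularity": row["granularity"],
                "category": row["category"],
                "estimate_id": row["estimate_id"],
                "delivery_strategy": "routine",
            }
        )
    obs = pd.DataFrame(obs_rows)

    if spec.emit_redundant_totals:
        totals = []
        for est in estimates:
            if not est["disaggregated"]:
                continue
            mask = obs["estimate_id"] == est["estimate_id"]
            sub = obs[mask]
            total = dict(sub.iloc[0])
            total["value_usd"] = float(sub["value_usd"].sum())
            for cat in CATEGORIES:
                total[f"inc_{cat}"] = int(cat in est["categories"])
            total["granularity"] = "total"
            total["category"] = "NA"
            totals.append(total)
        if totals:
            obs = pd.concat([obs, pd.DataFrame(totals)], ignore_index=True)

    obs = _append_pathologies(obs, covariates, spec, rng)

    truth = {
        "params": spec.params.to_dict(),
        "standardizer_means": {k: float(v) for k, v in means.items()},
        "standardizer_sds": {k: float(v) for k, v in sds.items()},
        "n_studies": spec.n_studies,
        "n_estimates": len(estimates),
        "n_total_only": sum(1 for e in estimates if not e["disaggregated"]),
        "n_category_rows": sum(len(e["cat_rows"]) for e in estimates),
        "n_analysis_rows": len(frame),
        "seed": spec.seed,
        "spec": {k: v for k, v in asdict(spec).items() if k != "params"},
    }
    analysis = frame.drop(columns=["tc_true"])
    return SimulatedData(
        observations=obs,
        covariates=covariates,
        truth=truth,
        analysis_frame=analysis,
        y=np.asarray(y, dtype=float),
        tc=np.asarray(tc, dtype=float),
    )


def _append_pathologies(
    obs: pd.DataFrame, covariates: pd.DataFrame, spec: ScenarioSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Optional malformed/excludable rows exercising every error path."""

    def template(value: float, **overrides) -> dict:
        row = {
            "study_id": "patho",
            "country_iso3": str(covariates["country_iso3"].iloc[0]),
            "base_year": spec.year_min,
            "value_usd": value,
            "price_year": spec.price_year,
            "inc_labor": 1,
            "inc_supply_chain": 1,
            "inc_service_delivery": 1,
            "inc_capital": 1,
            "cost_type": "economic",
            "scope": "programmatic",
            "granularity": "total",
            "category": "NA",
            "estimate_id": f"patho|{rng.integers(1 << 30)}",
            "delivery_strategy": "routine",
        }
        row.update(overrides)
        return row

    extra = []
    for _ in range(spec.n_zero_cost_rows):
        extra.append(template(0.0))
    for _ in range(spec.n_subcent_outliers):
        extra.append(template(float(rng.uniform(0.001, 0.009))))
    for _ in range(spec.n_outreach_rows):
        extra.append(template(float(rng.uniform(0.5, 5.0)), delivery_strategy="outreach"))
    for _ in range(spec.n_missing_covariate_rows):
        extra.append(template(float(rng.uniform(0.5, 5.0)), country_iso3="ZZZ"))
    if extra:
        obs = pd.concat([obs, pd.DataFrame(extra)], ignore_index=True)
    return obs


def make_fixture_tables(
    countries: int = 10,
    seed: int = 0,
    years: tuple[int, int] = (2001, 2018),
    monotone_cpi: bool = True,
) -> dict[str, pd.DataFrame]:
    """Internally consistent covariate, CPI/FX and region/income fixtures.

    Returns {"covariates", "currency", "lookups"}; CPI series are monotone
    increasing by default (per-country inflation 1-10%/year), FX a mild
    random walk around a country-specific level.
    """
    if countries < 1:
        raise ValueError("countries must be >= 1")
    rng = np.random.default_rng(seed)
    spec = ScenarioSpec(n_countries=countries, seed=seed)
    covariates = _country_panel(rng, spec, end_year=years[1])
    covariates = covariates[covariates["year"] >= years[0]].reset_index(drop=True)

    rows = []
    codes = _country_codes(countries)
    for code in codes:
        infl = rng.uniform(0.01, 0.10)
        fx_level = float(np.exp(rng.normal(np.log(100), 1.0)))
        cpi, fx = 100.0, fx_level
        for year in range(years[0], years[1] + 1):
            rows.append((code, year, cpi, fx))
            cpi *= 1 + (infl if monotone_cpi else rng.uniform(-0.02, 0.1))
            fx *= float(np.exp(rng.normal(0, 0.02)))
    currency = pd.DataFrame(rows, columns=["country_iso3", "year", "cpi_index", "fx_lcu_per_usd"])

    lookups = pd.DataFrame(
        {
            "country_iso3": codes,
            "who_region": [WHO_REGIONS[i % len(WHO_REGIONS)] for i in range(countries)],
            "income_level": rng.choice(INCOME_LEVELS, size=countries).tolist(),
        }
    )
    return {"covariates": covariates, "currency": currency, "lookups": lookups}
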