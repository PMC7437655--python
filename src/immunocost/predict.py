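"""Country-year cost-per-dose predictions, currency conversion, aggregation.

Predictions are programmatic (Single = 0), with all four cost categories
included, for economic (Econ = 1) or financial (Econ = 0) cost type.  For
every posterior draw the four category costs and their sum are evaluated at
the country-year covariates (standardized with the fitted-sample moments),
then summarized as the posterior mean and the equal-tailed 95% interval of
the deterministic expected cost — parameter uncertainty only, not Gamma
posterior-predictive draws.

Currency conversion follows the local-currency path: USD in the source price
year -> local currency at the source-year market exchange rate -> inflated to
the target year with the country CPI -> back to USD at the target-year rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import SchemaError
from .likelihood import CATEGORIES
from .model import GammaCostMetaRegression

COST_TYPE_CODES = {"financial": 0.0, "economic": 1.0}

CURRENCY_COLUMNS = ("country_iso3", "year", "cpi_index", "fx_lcu_per_usd")


class CurrencyTables:
    """Per-country CPI and market-exchange-rate series."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in CURRENCY_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"currency table missing columns: {missing}")
        if (frame["cpi_index"] <= 0).any() or (frame["fx_lcu_per_usd"] <= 0).any():
            raise ValueError("CPI and FX entries must be positive")
        self._table = frame.set_index(["country_iso3", "year"]).sort_index()

    @classmethod
    def from_csv(cls, path: str | Path) -> "CurrencyTables":
        return cls(pd.read_csv(path))

    def _row(self, country: str, year: int) -> pd.Series:
        try:
            return self._table.loc[(country, year)]
        except KeyError:
            raise KeyError(f"no CPI/FX entry for {country} {year}") from None

    def cpi(self, country: str, year: int) -> float:
        return float(self._row(country, year)["cpi_index"])

    def fx(self, country: str, year: int) -> float:
        return float(self._row(country, year)["fx_lcu_per_usd"])


def to_2018_usd(
    value: float | np.ndarray,
    country: str,
    price_year: int,
    tables: CurrencyTables,
    target_year: int = 2018,
):
    """Re-express USD of ``price_year`` in USD of ``target_year``.

    value * FX(price_year) * CPI(target)/CPI(price_year) / FX(target):
    convert to local currency at the source-year rate, inflate locally,
    convert back at the target-year rate.
    """
    factor = (
        tables.fx(country, price_year)
        * tables.cpi(country, target_year)
        / tables.cpi(country, price_year)
        / tables.fx(country, target_year)
    )
    return value * factor


def _prediction_frame(covariates: pd.DataFrame, cost_type: str) -> pd.DataFrame:
    if cost_type not in COST_TYPE_CODES:
        raise ValueError(f"cost_type must be 'economic' or 'financial', got {cost_type!r}")
    frame = pd.DataFrame(
        {
            "year": covariates["year"].astype(float),
            "doses": covariates["doses"].astype(float),
            "gdp_pc": covariates["gdp_pc_usd"].astype(float),
            "dtp3": covariates["dtp3"].astype(float),
            "pop": covariates["population"].astype(float),
            "econ": COST_TYPE_CODES[cost_type],
            "single": 0.0,
            "inc_labor": 1,
            "inc_supply_chain": 1,
            "inc_service_delivery": 1,
            "inc_capital": 1,
        }
    )
    return frame


def predict_country_year(
    model: GammaCostMetaRegression,
    covariates: pd.DataFrame,
    cost_type: str = "economic",
) -> np.ndarray:
    """Per-draw category costs, shape (n_draws, n_rows, 4).

    ``covariates`` is a covariate-table slice (country_iso3, year, doses,
    gdp_pc_usd, dtp3, population).  Years outside the fitted range trigger an
    extrapolation warning, not an error.
    """
    frame = _prediction_frame(covariates, cost_type)
    lo, hi = model.fitted_year_range_
    outside = (frame["year"] < lo) | (frame["year"] > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} prediction year(s) outside the fitted range "
            f"[{lo:.0f}, {hi:.0f}]; extrapolating",
            UserWarning,
        )
    return model.predict_draws(frame, per_category=True)


def summarize_draws(values: np.ndarray) -> tuple[float, float, float]:
    """Posterior mean and equal-tailed 95% interval of a draw vector."""
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(values.mean()), float(lo), float(hi)


def prediction_table(
    model: GammaCostMetaRegression,
    covariates: pd.DataFrame,
    cost_type: str = "economic",
    currency: CurrencyTables | None = None,
    price_year: int = 2016,
    target_year: int = 2018,
) -> pd.DataFrame:
    """Tidy per-country-year prediction table (category rows plus total).

    Totals are composed draw-wise — summed across categories within each
    draw before summarization — so the total mean equals the sum of the
    category means exactly.  With a currency table the model-scale prices
    (``price_year`` USD) are converted to ``target_year`` USD per country.
    """
    cat_draws = predict_country_year(model, covariates, cost_type)  # (D, n, 4)
    rows = []
    for j, (_, cov) in enumerate(covariates.iterrows()):
        country, year = str(cov["country_iso3"]), int(cov["year"])
        block = cat_draws[:, j, :]  # (D, 4)
        if currency is not None:
            block = to_2018_usd(block, country, price_year, currency, target_year)
        for k, cat in enumerate(CATEGORIES):
            mean, lo, hi = summarize_draws(block[:, k])
            rows.append((country, year, cost_type, cat, mean, lo, hi))
        mean, lo, hi = summarize_draws(block.sum(axis=1))
        rows.append((country, year, cost_type, "total", mean, lo, hi))
    out = pd.DataFrame(
        rows, columns=["country_iso3", "year", "cost_type", "category", "mean", "lo95", "hi95"]
    )
    out["currency"] = f"USD{target_year}" if currency is not None else f"USD{price_year}"
    return out


def weighted_aggregate(
    draws_by_country: Mapping[str, np.ndarray],
    weights: Mapping[str, float],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Population-weighted group averages of per-country draw vectors.

    ``draws_by_country`` maps country -> per-draw values (equal lengths);
    ``weights`` are populations in the target year; ``groups`` maps country
    -> group label (None aggregates everything into one "global" group).
    Weights are normalized within group; aggregation is per draw, then
    summarized.
    """
    countries = list(draws_by_country)
    missing = [c for c in countries if c not in weights]
    if missing:
        raise KeyError(f"missing aggregation weights for: {missing}")
    if groups is None:
        groups = {c: "global" for c in countries}
    rows = []
    for group in sorted(set(groups.get(c, "unclassified") for c in countries)):
        members = [c for c in countries if groups.get(c, "unclassified") == group]
        w = np.array([weights[c] for c in members], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"zero total weight in group {group!r}")
        w = w / w.sum()
        stacked = np.stack([np.asarray(draws_by_country[c], dtype=float) for c in members])
        per_draw = w @ stacked  # (n_draws,)
        mean, lo, hi = summarize_draws(per_draw)
        rows.append((group, len(members), mean, lo, hi))
    return pd.DataFrame(rows, columns=["group", "n_countries", "mean", "lo95", "hi95"])


def in_sample_check(
    model: GammaCostMetaRegression, X: pd.DataFrame, y: np.ndarray
) -> pd.DataFrame:
    """Predicted-vs-observed table for the fitted sample.

    One row per analysis observation: observed cost, posterior-mean expected
    cost under the observation's own Econ/Single/indicator settings, residual,
    and a category-pattern label for panel subsetting (all four categories,
    single-category rows, etc.).
    """
    pred = model.predict(X)
    y = np.asarray(y, dtype=float)
    inc = X[[f"inc_{c}" for c in CATEGORIES]].to_numpy(dtype=int)

    def pattern(row: np.ndarray) -> str:
        names = [c for c, on in zip(CATEGORIES, row) if on]
        if len(names) == 4:
            return "all_categories"
        if len(names) == 1:
            return f"{names[0]}_only"
        return "+".join(names)

    out = pd.DataFrame(
        {
            "observed": y,
            "predicted": pred,
            "residual": y - pred,
            "pattern": [pattern(r) for r in inc],
        }
    )
    for col in ("country", "year", "study_id", "estimate_id"):
        if col in X.columns:
            out[col] = X[col].to_numpy()
    return out
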