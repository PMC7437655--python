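"""Ingestion, validation, filtering and standardization of cost observations.

The observation schema is a flat CSV, one row per cost-per-dose datum:

    study_id, country_iso3, base_year, value_usd, price_year,
    inc_labor, inc_supply_chain, inc_service_delivery, inc_capital,
    cost_type {financial|economic|undefined}, scope {programmatic|single_antigen},
    granularity {total|category_row}, category {labor|supply_chain|
    service_delivery|capital|NA}

plus two optional columns: ``estimate_id`` (grouping key tying a total row to
its category disaggregation; derived from (study_id, cost_type, scope,
base_year) when absent) and ``delivery_strategy`` (routine|outreach|campaign,
default routine; non-routine rows are dropped by the inclusion filter).

Covariates are a country-year panel: country_iso3, year, doses, gdp_pc_usd,
dtp3, population.  The routine-schedule dose count falls back to the most
recent prior year when missing for the study year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .likelihood import CATEGORIES

COST_TYPES = {"financial": 0, "economic": 1, "undefined": 2}
SCOPES = {"programmatic": 0, "single_antigen": 1}
GRANULARITIES = ("total", "category_row")
DELIVERY_STRATEGIES = ("routine", "outreach", "campaign")

OBS_REQUIRED_COLUMNS = (
    "study_id",
    "country_iso3",
    "base_year",
    "value_usd",
    "price_year",
    "inc_labor",
    "inc_supply_chain",
    "inc_service_delivery",
    "inc_capital",
    "cost_type",
    "scope",
    "granularity",
    "category",
)

COV_REQUIRED_COLUMNS = ("country_iso3", "year", "doses", "gdp_pc_usd", "dtp3", "population")

#: continuous predictors standardized to mean 0, sd 1 on the analysis sample
CONTINUOUS_COLUMNS = ("year", "log_doses", "log_gdp", "dtp3", "log_pop")


class SchemaError(ValueError):
    """A required column is missing or a file cannot be parsed."""


class ValidationError(ValueError):
    """A row violates the observation/covariate invariants."""


class CovariateLookupError(KeyError):
    """No covariate record for an observation's country-year."""


@dataclass(frozen=True)
class CostObservation:
    """One cost-per-dose datum with its category pattern and descriptors."""

    study_id: str
    country: str
    base_year: int
    value_usd: float
    price_year: int
    include_labor: bool
    include_supply_chain: bool
    include_service_delivery: bool
    include_capital: bool
    cost_type: str        # financial / economic / undefined
    scope: str            # programmatic / single_antigen
    granularity: str      # total / category_row
    category: str | None = None
    estimate_id: str | None = None
    delivery_strategy: str = "routine"

    def __post_init__(self) -> None:
        if self.value_usd <= 0:
            raise ValidationError(
                f"value_usd must be strictly positive (Gamma support), got {self.value_usd}"
            )
        if self.cost_type not in COST_TYPES:
            raise ValidationError(f"unknown cost_type {self.cost_type!r}")
        if self.scope not in SCOPES:
            raise ValidationError(f"unknown scope {self.scope!r}")
        if self.granularity not in GRANULARITIES:
            raise ValidationError(f"unknown granularity {self.granularity!r}")
        if self.delivery_strategy not in DELIVERY_STRATEGIES:
            raise ValidationError(f"unknown delivery_strategy {self.delivery_strategy!r}")
        inc = self.indicators()
        if not any(inc):
            raise ValidationError("at least one cost-category indicator must be set")
        if self.granularity == "category_row":
            if sum(inc) != 1:
                raise ValidationError(
                    "a category_row observation must have exactly one indicator set"
                )
            if self.category not in CATEGORIES:
                raise ValidationError(
                    f"category_row must name its category, got {self.category!r}"
                )

    def indicators(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.include_labor,
            self.include_supply_chain,
            self.include_service_delivery,
            self.include_capital,
        )

    @property
    def econ_code(self) -> int:
        return COST_TYPES[self.cost_type]

    @property
    def single_code(self) -> int:
        return SCOPES[self.scope]

    @property
    def estimate_key(self) -> str:
        if self.estimate_id:
            return self.estimate_id
        return f"{self.study_id}|{self.cost_type}|{self.scope}|{self.base_year}"


def _as_bool(v) -> bool:
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("1", "true", "t", "yes"):
            return True
        if s in ("0", "false", "f", "no"):
            return False
        raise ValidationError(f"cannot interpret {v!r} as a boolean")
    return bool(int(v))


def load_observations(path: str | Path) -> list[CostObservation]:
    """Read and validate an observations CSV.

    Raises SchemaError for missing columns and ValidationError naming the
    offending row number (1-based, excluding the header) for bad rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    return observations_from_frame(frame)


def observations_from_frame(frame: pd.DataFrame) -> list[CostObservation]:
    missing = [c for c in OBS_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"observations table missing required columns: {missing}")
    out: list[CostObservation] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        try:
            cat = row["category"]
            if pd.isna(cat) or str(cat).upper() in ("NA", ""):
                cat = None
            obs = CostObservation(
                study_id=str(row["study_id"]),
                country=str(row["country_iso3"]),
                base_year=int(row["base_year"]),
                value_usd=float(row["value_usd"]),
                price_year=int(row["price_year"]),
                include_labor=_as_bool(row["inc_labor"]),
                include_supply_chain=_as_bool(row["inc_supply_chain"]),
                include_service_delivery=_as_bool(row["inc_service_delivery"]),
                include_capital=_as_bool(row["inc_capital"]),
                cost_type=str(row["cost_type"]),
                scope=str(row["scope"]),
                granularity=str(row["granularity"]),
                category=cat,
                estimate_id=(
                    str(row["estimate_id"])
                    if "estimate_id" in frame.columns and not pd.isna(row["estimate_id"])
                    else None
                ),
                delivery_strategy=(
                    str(row["delivery_strategy"])
                    if "delivery_strategy" in frame.columns
                    and not pd.isna(row["delivery_strategy"])
                    else "routine"
                ),
            )
            out.append(obs)
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx + 1}: {exc}")
    if errors:
        raise ValidationError("invalid observation rows:\n" + "\n".join(errors))
    return out


def observations_to_frame(observations: Iterable[CostObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append(
            {
                "study_id": o.study_id,
                "country_iso3": o.country,
                "base_year": o.base_year,
                "value_usd": o.value_usd,
                "price_year": o.price_year,
                "inc_labor": int(o.include_labor),
                "inc_supply_chain": int(o.include_supply_chain),
                "inc_service_delivery": int(o.include_service_delivery),
                "inc_capital": int(o.include_capital),
                "cost_type": o.cost_type,
                "scope": o.scope,
                "granularity": o.granularity,
                "category": o.category if o.category else "NA",
                "estimate_id": o.estimate_key,
                "delivery_strategy": o.delivery_strategy,
            }
        )
    return pd.DataFrame(rows)


def apply_inclusion_filters(
    observations: Sequence[CostObservation],
    exclude_outliers: bool = False,
    outlier_threshold: float = 0.01,
) -> tuple[list[CostObservation], pd.DataFrame]:
    """Keep routine fixed-facility delivery rows; optionally drop sub-$0.01
    outliers (the sensitivity re-specification).

    Returns the retained rows and an exclusion log with one reason per
    dropped row.  Raises ValidationError if nothing survives.
    """
    kept: list[CostObservation] = []
    log_rows = []
    for i, obs in enumerate(observations):
        reason = None
        if obs.delivery_strategy != "routine":
            reason = f"non_routine_delivery:{obs.delivery_strategy}"
        elif exclude_outliers and obs.value_usd < outlier_threshold:
            reason = f"outlier_below_{outlier_threshold}"
        if reason is None:
            kept.append(obs)
        else:
            log_rows.append(
                {
                    "row": i,
                    "study_id": obs.study_id,
                    "estimate_id": obs.estimate_key,
                    "value_usd": obs.value_usd,
                    "reason": reason,
                }
            )
    if not kept:
        raise ValidationError("all observations excluded; nothing to fit")
    log = pd.DataFrame(log_rows, columns=["row", "study_id", "estimate_id", "value_usd", "reason"])
    return kept, log


def disaggregate(observations: Sequence[CostObservation]) -> list[CostObservation]:
    """Resolve total vs category granularity within each estimate.

    When an estimate carries category rows, its total row is redundant (the
    categories are the higher-granularity observations) and is dropped;
    estimates reported only as a total keep their total row.  The output
    count is therefore (total-only estimates) + (category rows).
    """
    has_cat: set[str] = {
        o.estimate_key for o in observations if o.granularity == "category_row"
    }
    out: list[CostObservation] = []
    for obs in observations:
        if obs.granularity == "total" and obs.estimate_key in has_cat:
            continue
        out.append(obs)
    # double-count guard: no estimate may retain both granularities
    seen_total = {o.estimate_key for o in out if o.granularity == "total"}
    if seen_total & has_cat:
        raise ValidationError(
            f"estimates retain both total and category rows: {sorted(seen_total & has_cat)}"
        )
    return out


def load_covariates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    missing = [c for c in COV_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"covariates table missing required columns: {missing}")
    bad = frame[
        (frame["gdp_pc_usd"] <= 0)
        | (frame["population"] <= 0)
        | (frame["dtp3"] < 0)
        | (frame["dtp3"] > 1)
        | (frame["doses"].notna() & (frame["doses"] < 1))
    ]
    if len(bad):
        raise ValidationError(
            f"covariate rows violate invariants (rows {list(bad.index + 1)}): "
            "need doses>=1, gdp_pc_usd>0, 0<=dtp3<=1, population>0"
        )
    return frame


def lookup_covariates(
    covariates: pd.DataFrame, country: str, year: int, schedule_gap_warn: int = 3
) -> dict[str, float]:
    """Country-year covariate lookup with the routine-schedule fallback.

    GDP, DTP3 and population must exist for the exact year; a missing dose
    count falls back to the most recent prior year (warning when the gap
    exceeds ``schedule_gap_warn`` years).
    """
    sel = covariates[(covariates["country_iso3"] == country) & (covariates["year"] == year)]
    if sel.empty:
        raise CovariateLookupError(f"no covariate record for {country} {year}")
    row = sel.iloc[0]
    doses = row["doses"]
    if pd.isna(doses):
        prior = covariates[
            (covariates["country_iso3"] == country)
            & (covariates["year"] < year)
            & covariates["doses"].notna()
        ].sort_values("year")
        if prior.empty:
            raise CovariateLookupError(
                f"no routine-schedule dose count available for {country} at or before {year}"
            )
        fallback = prior.iloc[-1]
        gap = year - int(fallback["year"])
        if gap > schedule_gap_warn:
            warnings.warn(
                f"schedule fallback for {country} {year} uses year {int(fallback['year'])} "
                f"({gap} years earlier)",
                UserWarning,
            )
        doses = fallback["doses"]
    return {
        "doses": float(doses),
        "gdp_pc": float(row["gdp_pc_usd"]),
        "dtp3": float(row["dtp3"]),
        "pop": float(row["population"]),
    }


class CovariateStandardizer(TransformerMixin, BaseEstimator):
    """Z-score the five continuous predictors (Year, log Doses, log GDP,
    DTP3, log Pop) with moments from the analysis sample.

    Fitted moments live in ``means_`` / ``sds_`` and are the standardization
    parameters reused verbatim for prediction covariates — prediction data
    never re-fits them.
    """

    def __init__(self, columns: Sequence[str] = CONTINUOUS_COLUMNS):
        self.columns = tuple(columns)

    def fit(self, frame: pd.DataFrame, y=None) -> "CovariateStandardizer":
        missing = [c for c in self.columns if c not in frame.columns]
        if missing:
            raise SchemaError(f"standardizer input missing columns: {missing}")
        means = frame[list(self.columns)].mean()
        sds = frame[list(self.columns)].std(ddof=0)
        if (sds <= 0).any():
            bad = list(sds[sds <= 0].index)
            raise ValidationError(f"zero-variance continuous columns: {bad}")
        self.means_ = means
        self.sds_ = sds
        self.n_features_in_ = len(self.columns)
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for c in self.columns:
            out[c] = (out[c] - self.means_[c]) / self.sds_[c]
        return out

    def inverse_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for c in self.columns:
            out[c] = out[c] * self.sds_[c] + self.means_[c]
        return out


def derive_continuous(frame: pd.DataFrame) -> pd.DataFrame:
    """Add natural-log transforms: log_doses, log_gdp, log_pop."""
    out = frame.copy()
    out["log_doses"] = np.log(out["doses"])
    out["log_gdp"] = np.log(out["gdp_pc"])
    out["log_pop"] = np.log(out["pop"])
    return out


def build_analysis_frame(
    observations: Sequence[CostObservation], covariates: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Join analysis observations to their country-year covariates.

    Returns (X, y): a frame with the raw model inputs (year, doses, gdp_pc,
    dtp3, pop, econ, single, inc_*) plus provenance columns, and the observed
    costs.  Standardization happens downstream, inside the estimator, so the
    moments always come from exactly the rows being fitted.
    """
    rows, y = [], []
    for obs in observations:
        cov = lookup_covariates(covariates, obs.country, obs.base_year)
        inc = obs.indicators()
        rows.append(
            {
                "study_id": obs.study_id,
                "estimate_id": obs.estimate_key,
                "country": obs.country,
                "year": float(obs.base_year),
                "doses": cov["doses"],
                "gdp_pc": cov["gdp_pc"],
                "dtp3": cov["dtp3"],
                "pop": cov["pop"],
                "econ": float(obs.econ_code),
                "single": float(obs.single_code),
                "inc_labor": int(inc[0]),
                "inc_supply_chain": int(inc[1]),
                "inc_service_delivery": int(inc[2]),
                "inc_capital": int(inc[3]),
                "granularity": obs.granularity,
                "category": obs.category if obs.category else "NA",
                "price_year": obs.price_year,
            }
        )
        y.append(obs.value_usd)
    return pd.DataFrame(rows), np.asarray(y, dtype=float)


def standardize(
    observations: Sequence[CostObservation], covariates: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, CovariateStandardizer]:
    """Build the standardized design frame for the analysis observations.

    Convenience wrapper over build_analysis_frame + derive_continuous +
    CovariateStandardizer; returns (standardized frame, y, fitted
    standardizer).
    """
    X, y = build_analysis_frame(observations, covariates)
    X = derive_continuous(X)
    std = CovariateStandardizer().fit(X)
    return std.transform(X), y, std
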