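"""End-to-end orchestration: ingest -> fit -> diagnose -> predict ->
aggregate -> effects -> reports, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    apply_inclusion_filters,
    build_analysis_frame,
    disaggregate,
    load_covariates,
    load_observations,
)
from .effects import standard_first_differences
from .model import GammaCostMetaRegression
from .predict import CurrencyTables, in_sample_check, prediction_table, weighted_aggregate
from .sampler import ConvergenceWarning


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    observations: str
    covariates: str
    outdir: str
    currency: str | None = None
    lookups: str | None = None
    prior_variant: str = "default"
    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2500
    seed: int = 0
    exclude_outliers: bool = False
    cost_types: tuple[str, ...] = ("economic", "financial")
    years: tuple[int, int] = (2009, 2018)
    price_year: int = 2016
    target_year: int = 2018

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "cost_types" in raw:
            raw["cost_types"] = tuple(raw["cost_types"])
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cost_types"] = list(self.cost_types)
        d["years"] = list(self.years)
        return d


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Any stage failure raises PipelineError naming the stage; CLI maps that
    onto a nonzero exit code.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
        return _Ctx()

    with stage("load"):
        observations = load_observations(config.observations)
        covariates = load_covariates(config.covariates)
        currency = CurrencyTables.from_csv(config.currency) if config.currency else None
        lookups = pd.read_csv(config.lookups) if config.lookups else None

    with stage("filter"):
        kept, exclusions = apply_inclusion_filters(
            observations, exclude_outliers=config.exclude_outliers
        )
        exclusions.to_csv(out / "exclusions.csv", index=False)
        outputs["exclusions"] = "exclusions.csv"

    with stage("disaggregate"):
        analysis_obs = disaggregate(kept)

    with stage("design"):
        X, y = build_analysis_frame(analysis_obs, covariates)

    convergence_warned = False
    with stage("fit"):
        model = GammaCostMetaRegression(
            prior_variant=config.prior_variant,
            chains=config.chains,
            iterations=config.iterations,
            burn_in=config.burn_in,
            seed=config.seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model.fit(X, y)
        convergence_warned = any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        model.save(out / "model")
        outputs["draws"] = "model/draws.csv"
        outputs["model_meta"] = "model/model.json"
        (out / "diagnostics.json").write_text(json.dumps(model.diagnostics_, indent=2))
        outputs["diagnostics"] = "diagnostics.json"

    with stage("predict"):
        year_lo, year_hi = config.years
        pred_cov = covariates[
            (covariates["year"] >= year_lo) & (covariates["year"] <= year_hi)
        ].reset_index(drop=True)
        tables = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for ct in config.cost_types:
                tables.append(
                    prediction_table(
                        model,
                        pred_cov,
                        cost_type=ct,
                        currency=currency,
                        price_year=config.price_year,
                        target_year=config.target_year,
                    )
                )
        predictions = pd.concat(tables, ignore_index=True)
        predictions.to_csv(out / "predictions.csv", index=False)
        outputs["predictions"] = "predictions.csv"

    with stage("aggregate"):
        rows = []
        from .predict import predict_country_year, to_2018_usd

        for ct in config.cost_types:
            for year in range(year_lo, year_hi + 1):
                cov_y = covariates[covariates["year"] == year].reset_index(drop=True)
                if cov_y.empty:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    cat_draws = predict_country_year(model, cov_y, ct)
                totals = cat_draws.sum(axis=2)  # (D, n)
                draws_by_country, weights = {}, {}
                for j, (_, c) in enumerate(cov_y.iterrows()):
                    code = str(c["country_iso3"])
                    vals = totals[:, j]
                    if currency is not None:
                        vals = to_2018_usd(
                            vals, code, config.price_year, currency, config.target_year
                        )
                    draws_by_country[code] = vals
                    weights[code] = float(c["population"])
                groupings = {"global": None}
                if lookups is not None:
                    groupings["who_region"] = dict(
                        zip(lookups["country_iso3"], lookups["who_region"])
                    )
                    groupings["income_level"] = dict(
                        zip(lookups["country_iso3"], lookups["income_level"])
                    )
                for gname, gmap in groupings.items():
                    agg = weighted_aggregate(draws_by_country, weights, gmap)
                    for _, r in agg.iterrows():
                        rows.append(
                            (gname, r["group"], year, ct, r["n_countries"],
                             r["mean"], r["lo95"], r["hi95"])
                        )
        aggregates = pd.DataFrame(
            rows,
            columns=["grouping", "group", "year", "cost_type",
                     "n_countries", "mean", "lo95", "hi95"],
        )
        aggregates.to_csv(out / "aggregates.csv", index=False)
        outputs["aggregates"] = "aggregates.csv"

    with stage("effects"):
        fd = standard_first_differences(model.draws_, model.standardizer_, model.mean_doses_)
        fd.to_csv(out / "first_differences.csv", index=False)
        outputs["first_differences"] = "first_differences.csv"

    with stage("in_sample"):
        check = in_sample_check(model, X, y)
        check.to_csv(out / "in_sample.csv", index=False)
        outputs["in_sample"] = "in_sample.csv"

    with stage("manifest"):
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config_hash(config),
            "outputs": outputs,
            "n_observations_loaded": len(observations),
            "n_excluded": len(exclusions),
            "n_analysis_rows": len(X),
            "max_rhat": model.diagnostics_["max_rhat"],
            "convergence_warning": convergence_warned,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
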