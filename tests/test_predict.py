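"""Country-year predictions, currency conversion, aggregation, fit checks."""

import numpy as np
import pandas as pd
import pytest

import immunocost as ic
from immunocost.predict import prediction_table, summarize_draws
from immunocost.simulate import table_params

from conftest import make_degenerate_model


@pytest.fixture(scope="module")
def flat_currency():
    frame = pd.DataFrame(
        {
            "country_iso3": ["AAA"] * 3,
            "year": [2016, 2017, 2018],
            "cpi_index": [100.0, 100.0, 100.0],
            "fx_lcu_per_usd": [50.0, 50.0, 50.0],
        }
    )
    return ic.CurrencyTables(frame)


def _currency(cpi_by_year, fx_by_year, country="AAA"):
    years = sorted(cpi_by_year)
    return ic.CurrencyTables(
        pd.DataFrame(
            {
                "country_iso3": [country] * len(years),
                "year": years,
                "cpi_index": [cpi_by_year[y] for y in years],
                "fx_lcu_per_usd": [fx_by_year[y] for y in years],
            }
        )
    )


class TestCurrencyConversion:
    def test_flat_series_is_identity(self, flat_currency):
        assert ic.to_2018_usd(3.5, "AAA", 2016, flat_currency) == pytest.approx(3.5)

    def test_pure_inflation_doubles_value(self):
        tables = _currency({2016: 100, 2018: 200}, {2016: 50, 2018: 50})
        assert ic.to_2018_usd(1.0, "AAA", 2016, tables) == pytest.approx(2.0)

    def test_inflation_offset_by_depreciation(self):
        # CPI ratio 1.10 against an FX move 100 -> 110 cancels exactly
        tables = _currency({2016: 100, 2018: 110}, {2016: 100, 2018: 110})
        assert ic.to_2018_usd(1.0, "AAA", 2016, tables) == pytest.approx(1.0)
        # explicit local-currency path arithmetic
        lcu_2016 = 1.0 * 100
        lcu_2018 = lcu_2016 * 110 / 100
        assert lcu_2018 / 110 == pytest.approx(1.0)

    def test_missing_year_named_in_error(self, flat_currency):
        with pytest.raises(KeyError, match="AAA 2005"):
            ic.to_2018_usd(1.0, "AAA", 2005, flat_currency)

    def test_conversion_commutes_with_aggregation(self):
        # common multiplicative factor: convert-then-average == average-then-convert
        tables = _currency({2016: 100, 2018: 150}, {2016: 10, 2018: 12})
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 5.0, 20)
        a = np.mean([ic.to_2018_usd(v, "AAA", 2016, tables) for v in vals])
        b = ic.to_2018_usd(float(np.mean(vals)), "AAA", 2016, tables)
        assert a == pytest.approx(b)

    def test_invalid_entries_rejected(self):
        frame = pd.DataFrame(
            {"country_iso3": ["AAA"], "year": [2016], "cpi_index": [-1.0],
             "fx_lcu_per_usd": [50.0]}
        )
        with pytest.raises(ValueError, match="positive"):
            ic.CurrencyTables(frame)


def _one_country_covariates(year=2016, **overrides):
    row = dict(country_iso3="AAA", year=year, doses=12, gdp_pc_usd=1550.0,
               dtp3=0.88, population=5e7)
    row.update(overrides)
    return pd.DataFrame([row])


class TestCountryYearPredictions:
    def test_degenerate_draws_collapse_intervals(self):
        model = make_degenerate_model(table_params())
        table = prediction_table(model, _one_country_covariates())
        assert (table["hi95"] - table["lo95"]).abs().max() < 1e-12
        assert np.allclose(table["mean"], table["lo95"])

    def test_degenerate_point_prediction_matches_equations(self):
        model = make_degenerate_model(table_params())
        cov = _one_country_covariates(year=0, doses=1, gdp_pc_usd=1.0, dtp3=0.0,
                                      population=1)
        # all standardized covariates are zero -> economic total is
        # exp(beta_econ) times the sum of the category intercept exps
        table = prediction_table(model, cov, cost_type="economic")
        want = np.exp(-0.06) * sum(np.exp(v) for v in (0.08, -0.97, -0.07, -1.16))
        got = table.loc[table["category"] == "total", "mean"].iloc[0]
        assert got == pytest.approx(want)

    def test_category_means_sum_to_total_mean(self, fitted_model, small_sim):
        cov = small_sim.covariates[small_sim.covariates["year"] == 2016].head(4)
        table = prediction_table(fitted_model, cov)
        for (country, year), grp in table.groupby(["country_iso3", "year"]):
            cats = grp.loc[grp["category"] != "total", "mean"].sum()
            total = grp.loc[grp["category"] == "total", "mean"].iloc[0]
            assert abs(cats - total) < 1e-9 * max(1.0, total)

    def test_economic_financial_ratio_constant_across_categories(self, fitted_model, small_sim):
        cov = small_sim.covariates[small_sim.covariates["year"] == 2016].head(2)
        econ = ic.predict_country_year(fitted_model, cov, "economic")
        fin = ic.predict_country_year(fitted_model, cov, "financial")
        ratio = econ / fin  # (D, n, 4): within a draw, identical across categories
        spread = ratio.max(axis=2) - ratio.min(axis=2)
        assert np.abs(spread).max() < 1e-12

    def test_extrapolation_warns_not_errors(self, fitted_model):
        cov = _one_country_covariates(year=2030)
        with pytest.warns(UserWarning, match="outside the fitted range"):
            ic.predict_country_year(fitted_model, cov)


class TestWeightedAggregate:
    def test_single_country_identity(self):
        draws = {"AAA": np.array([1.0, 2.0, 3.0])}
        out = ic.weighted_aggregate(draws, {"AAA": 5e6})
        assert out["mean"].iloc[0] == pytest.approx(2.0)

    def test_equal_weights_average(self):
        c = np.array([1.0, 1.0, 1.0])
        out = ic.weighted_aggregate({"A": c, "B": 3 * c}, {"A": 10.0, "B": 10.0})
        assert out["mean"].iloc[0] == pytest.approx(2.0)

    def test_aggregate_bounded_by_members(self):
        rng = np.random.default_rng(1)
        draws = {f"C{i}": rng.uniform(0.5, 5.0, 100) for i in range(6)}
        out = ic.weighted_aggregate(draws, {k: 1.0 for k in draws})
        stacked = np.stack(list(draws.values()))
        per_draw = out["mean"].iloc[0]
        assert stacked.min(axis=0).mean() <= per_draw <= stacked.max(axis=0).mean()

    def test_grouping_partitions_countries(self):
        draws = {k: np.ones(10) * v for k, v in [("A", 1.0), ("B", 2.0), ("C", 6.0)]}
        out = ic.weighted_aggregate(
            draws, {"A": 1.0, "B": 1.0, "C": 1.0}, {"A": "g1", "B": "g1", "C": "g2"}
        )
        got = dict(zip(out["group"], out["mean"]))
        assert got == {"g1": pytest.approx(1.5), "g2": pytest.approx(6.0)}

    def test_zero_weight_and_missing_weight_errors(self):
        draws = {"A": np.ones(5)}
        with pytest.raises(ValueError, match="zero total weight"):
            ic.weighted_aggregate(draws, {"A": 0.0})
        with pytest.raises(KeyError, match="missing aggregation weights"):
            ic.weighted_aggregate(draws, {})


class TestInSampleCheck:
    def test_one_row_per_observation(self, fitted_model, small_sim):
        table = ic.in_sample_check(fitted_model, small_sim.analysis_frame, small_sim.y)
        assert len(table) == len(small_sim.y)
        assert {"observed", "predicted", "residual", "pattern"} <= set(table.columns)

    def test_perfect_fit_residuals_vanish(self, small_sim):
        model = make_degenerate_model(table_params())
        X = small_sim.analysis_frame
        # standardize exactly as the generator did, then feed y = tc
        model.standardizer_.means_ = pd.Series(small_sim.truth["standardizer_means"])
        model.standardizer_.sds_ = pd.Series(small_sim.truth["standardizer_sds"])
        table = ic.in_sample_check(model, X, small_sim.tc)
        assert np.abs(table["residual"]).max() < 1e-9

    def test_self_consistency_mean_residual(self, fitted_model, small_sim):
        # simulate data from the fitted model's own mean parameters: the
        # posterior-mean prediction should be unbiased for it
        rng = np.random.default_rng(8)
        pred = fitted_model.predict(small_sim.analysis_frame)
        alpha = float(fitted_model.posterior_mean_["alpha"])
        reps = np.array(
            [rng.gamma(alpha, pred / alpha).mean() - pred.mean() for _ in range(200)]
        )
        sim_y = rng.gamma(alpha, pred / alpha)
        table = ic.in_sample_check(fitted_model, small_sim.analysis_frame, sim_y)
        assert abs(table["residual"].mean()) < 4 * reps.std()

    def test_pattern_labels(self, fitted_model, small_sim):
        table = ic.in_sample_check(fitted_model, small_sim.analysis_frame, small_sim.y)
        pats = set(table["pattern"])
        assert any(p.endswith("_only") for p in pats)


class TestSummaries:
    def test_summarize_draws_orders_bounds(self):
        mean, lo, hi = summarize_draws(np.random.default_rng(0).normal(2, 1, 5000))
        assert lo <= mean <= hi
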