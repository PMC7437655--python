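"""Ingestion, filtering, disaggregation and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import immunocost as ic
from immunocost.data import (
    CovariateStandardizer,
    SchemaError,
    ValidationError,
    derive_continuous,
    lookup_covariates,
    observations_from_frame,
    observations_to_frame,
)

from conftest import observation_kwargs


def _obs(**kw) -> ic.CostObservation:
    return ic.CostObservation(**observation_kwargs(**kw))


def _category_row(study, category, value=1.0, **kw):
    inc = {f"include_{c}": c == category for c in ic.CATEGORIES}
    return _obs(
        study_id=study,
        granularity="category_row",
        category=category,
        value_usd=value,
        **inc,
        **kw,
    )


class TestObservationValidation:
    def test_well_formed_csv_roundtrip(self, tmp_path):
        obs = [_obs(study_id=f"s{i}") for i in range(3)]
        path = tmp_path / "obs.csv"
        observations_to_frame(obs).to_csv(path, index=False)
        loaded = ic.load_observations(path)
        assert len(loaded) == 3
        assert loaded[0].value_usd == pytest.approx(1.5)

    @pytest.mark.parametrize("value", [0.0, -1.0])
    def test_nonpositive_cost_rejected(self, value):
        with pytest.raises(ValidationError, match="positive"):
            _obs(value_usd=value)

    def test_invalid_rows_reported_with_row_numbers(self):
        frame = observations_to_frame([_obs(), _obs(study_id="s2")])
        frame.loc[1, "value_usd"] = 0.0
        with pytest.raises(ValidationError, match="row 2"):
            observations_from_frame(frame)

    def test_missing_column_is_schema_error(self):
        frame = observations_to_frame([_obs()]).drop(columns=["cost_type"])
        with pytest.raises(SchemaError, match="cost_type"):
            observations_from_frame(frame)

    def test_no_category_included_rejected(self):
        with pytest.raises(ValidationError, match="at least one"):
            _obs(
                include_labor=False,
                include_supply_chain=False,
                include_service_delivery=False,
                include_capital=False,
            )

    def test_category_row_needs_exactly_one_indicator(self):
        with pytest.raises(ValidationError, match="exactly one"):
            _obs(granularity="category_row", category="labor")


def table2_portfolio() -> list:
    """A portfolio shaped like the real evidence base: 34 total-only
    estimates plus 18 disaggregated estimates contributing 85 category rows
    (duplicate-category rows stand in for multi-site reporting), each with
    its redundant total."""
    obs = []
    for i in range(34):
        obs.append(_obs(study_id=f"tot{i}", estimate_id=f"tot{i}"))
    counts = [5] * 13 + [4] * 5  # sums to 85
    for j, k in enumerate(counts):
        cats = [ic.CATEGORIES[m % 4] for m in range(k)]
        for c in cats:
            obs.append(_category_row(f"dis{j}", c, estimate_id=f"dis{j}"))
        inc = {f"include_{c}": c in cats for c in ic.CATEGORIES}
        obs.append(_obs(study_id=f"dis{j}", estimate_id=f"dis{j}", **inc))
    return obs


class TestDisaggregate:
    def test_total_dropped_when_categories_present(self):
        obs = [_category_row("s1", c, estimate_id="e1") for c in ic.CATEGORIES]
        obs.append(_obs(estimate_id="e1"))
        out = ic.disaggregate(obs)
        assert len(out) == 4
        assert all(o.granularity == "category_row" for o in out)

    def test_evidence_base_composition_yields_119_rows(self):
        out = ic.disaggregate(table2_portfolio())
        assert len(out) == 34 + 85 == 119
        assert sum(o.granularity == "total" for o in out) == 34

    def test_noop_without_category_rows(self):
        obs = [_obs(study_id=f"s{i}", estimate_id=f"e{i}") for i in range(5)]
        assert ic.disaggregate(obs) == obs


class TestInclusionFilters:
    def test_outreach_excluded_with_reason(self):
        obs = [_obs(), _obs(study_id="s2", delivery_strategy="outreach")]
        kept, log = ic.apply_inclusion_filters(obs)
        assert len(kept) == 1
        assert log["reason"].iloc[0].startswith("non_routine")

    def test_subcent_outlier_dropped_only_under_flag(self):
        obs = [_obs(), _obs(study_id="s2", value_usd=0.005)]
        kept_off, log_off = ic.apply_inclusion_filters(obs, exclude_outliers=False)
        assert kept_off == obs and log_off.empty
        kept_on, log_on = ic.apply_inclusion_filters(obs, exclude_outliers=True)
        assert len(kept_on) == 1
        assert "outlier" in log_on["reason"].iloc[0]

    def test_empty_result_is_hard_error(self):
        with pytest.raises(ValidationError, match="nothing to fit"):
            ic.apply_inclusion_filters([_obs(delivery_strategy="outreach")])

    def test_row_counts_conserved(self):
        obs = [_obs(study_id=f"s{i}") for i in range(4)]
        obs += [_obs(study_id="x", delivery_strategy="campaign")]
        kept, log = ic.apply_inclusion_filters(obs)
        assert len(kept) + len(log) == len(obs)
        assert log["reason"].notna().all()

    @given(
        strategies=st.lists(
            st.sampled_from(["routine", "outreach", "campaign"]), min_size=1, max_size=12
        ),
        disagg=st.lists(st.booleans(), min_size=1, max_size=12),
    )
    def test_filter_and_disaggregate_commute(self, strategies, disagg):
        pairs = list(zip(strategies, disagg))
        obs = []
        for i, (strat, d) in enumerate(pairs):
            if d:
                obs.append(_category_row(f"s{i}", "labor", estimate_id=f"e{i}",
                                         delivery_strategy=strat))
                obs.append(_obs(study_id=f"s{i}", estimate_id=f"e{i}",
                                delivery_strategy=strat))
            else:
                obs.append(_obs(study_id=f"s{i}", estimate_id=f"e{i}",
                                delivery_strategy=strat))
        if all(s != "routine" for s, _ in pairs):
            return  # both orders raise the empty-result error
        a = ic.disaggregate(ic.apply_inclusion_filters(obs)[0])
        b, _ = ic.apply_inclusion_filters(ic.disaggregate(obs))
        assert a == b


class TestCovariates:
    def test_missing_covariate_names_country_year(self, small_sim):
        with pytest.raises(KeyError, match="ZZZ 2010"):
            lookup_covariates(small_sim.covariates, "ZZZ", 2010)

    def test_schedule_fallback_uses_most_recent_prior_year(self):
        cov = pd.DataFrame(
            {
                "country_iso3": ["AAA"] * 3,
                "year": [2008, 2009, 2010],
                "doses": [10.0, np.nan, np.nan],
                "gdp_pc_usd": [1000.0] * 3,
                "dtp3": [0.9] * 3,
                "population": [1e6] * 3,
            }
        )
        assert lookup_covariates(cov, "AAA", 2010)["doses"] == 10.0

    def test_schedule_fallback_warns_on_long_gap(self):
        cov = pd.DataFrame(
            {
                "country_iso3": ["AAA"] * 6,
                "year": list(range(2005, 2011)),
                "doses": [10.0] + [np.nan] * 5,
                "gdp_pc_usd": [1000.0] * 6,
                "dtp3": [0.9] * 6,
                "population": [1e6] * 6,
            }
        )
        with pytest.warns(UserWarning, match="5 years earlier"):
            lookup_covariates(cov, "AAA", 2010)

    def test_invalid_covariates_rejected(self, tmp_path):
        frame = pd.DataFrame(
            {
                "country_iso3": ["AAA"],
                "year": [2010],
                "doses": [12],
                "gdp_pc_usd": [-5.0],
                "dtp3": [0.9],
                "population": [1e6],
            }
        )
        path = tmp_path / "cov.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            ic.load_covariates(path)


class TestStandardization:
    def test_columns_centered_and_scaled(self, small_sim):
        obs = observations_from_frame(small_sim.observations)
        kept, _ = ic.apply_inclusion_filters(obs)
        analysis = ic.disaggregate(kept)
        frame, y, std = ic.standardize(analysis, small_sim.covariates)
        for col in std.columns:
            assert abs(frame[col].mean()) < 1e-10
            assert abs(frame[col].std(ddof=0) - 1) < 1e-10
        assert len(frame) == len(y)

    def test_round_trip_identity(self, small_sim):
        work = derive_continuous(
            small_sim.analysis_frame[["year", "doses", "gdp_pc", "dtp3", "pop"]]
        )
        std = CovariateStandardizer().fit(work)
        back = std.inverse_transform(std.transform(work))
        for col in std.columns:
            assert np.allclose(back[col], work[col], atol=1e-12)

    def test_zero_variance_column_rejected(self):
        frame = pd.DataFrame({c: np.ones(5) for c in CovariateStandardizer().columns})
        with pytest.raises(ValidationError, match="zero-variance"):
            CovariateStandardizer().fit(frame)

    def test_generated_dose_moments_near_scenario(self):
        sim = ic.simulate_dataset(ic.ScenarioSpec(seed=5, n_studies=120, n_countries=120))
        doses = sim.analysis_frame.groupby("country")["doses"].first()
        # Monte-Carlo tolerance: sd/sqrt(n) on the mean, generous on the sd
        assert abs(doses.mean() - 12) < 3 * 3 / np.sqrt(len(doses)) + 0.5
        assert 1.5 < doses.std() < 4.5
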