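import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import immunocost as ic
from immunocost.data import CovariateStandardizer

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim() -> ic.SimulatedData:
    """Default-conditions portfolio: ~29 studies, ~50 estimates."""
    return ic.simulate_dataset(ic.ScenarioSpec(seed=1))


@pytest.fixture(scope="session")
def fitted_model(small_sim) -> ic.GammaCostMetaRegression:
    """A modest-length fit reused across prediction/effects tests."""
    model = ic.GammaCostMetaRegression(chains=4, iterations=1500, burn_in=750, seed=3)
    with pytest.warns(Warning):  # short chains may trip the Rhat threshold
        model.fit(small_sim.analysis_frame, small_sim.y)
    return model


@pytest.fixture(scope="session")
def fixture_tables() -> dict:
    return ic.make_fixture_tables(countries=6, seed=0)


def make_degenerate_model(
    params: ic.ModelParams,
    n_draws: int = 50,
    means: dict | None = None,
    sds: dict | None = None,
) -> ic.GammaCostMetaRegression:
    """A 'fitted' estimator whose posterior is a point mass at ``params``.

    Useful for exercising prediction/summarization logic with zero posterior
    variance: every interval collapses onto the deterministic prediction.
    """
    est = ic.GammaCostMetaRegression()
    std = CovariateStandardizer()
    cols = std.columns
    std.means_ = pd.Series(means or {c: 0.0 for c in cols})
    std.sds_ = pd.Series(sds or {c: 1.0 for c in cols})
    std.n_features_in_ = len(cols)
    est.standardizer_ = std
    est.slope_names_ = ic.DEFAULT_SLOPES
    est.param_names_ = list(params.to_dict())
    vec = params.to_vector()
    frame = pd.DataFrame(np.tile(vec, (n_draws, 1)), columns=est.param_names_)
    frame.insert(0, "iteration", np.arange(n_draws) % (n_draws // 2))
    frame.insert(0, "chain", np.repeat([0, 1], n_draws // 2))
    est.draws_ = ic.PosteriorDraws(draws=frame, param_names=est.param_names_)
    est.fitted_year_range_ = (-np.inf, np.inf)
    est.mean_doses_ = 12.0
    est.econ_coding = "numeric"
    return est


def observation_kwargs(**overrides) -> dict:
    """A valid total-granularity observation, overridable per test."""
    base = dict(
        study_id="s1",
        country="C00",
        base_year=2010,
        value_usd=1.5,
        price_year=2016,
        include_labor=True,
        include_supply_chain=True,
        include_service_delivery=True,
        include_capital=True,
        cost_type="economic",
        scope="programmatic",
        granularity="total",
    )
    base.update(overrides)
    return base
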