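"""First differences: posterior percent change in cost per dose for a
specified change in one predictor, holding the others fixed.

Because the model is log-linear, the ratio of predictions at x and x + delta
does not depend on the baseline x: the percent change for predictor k is

    100 * (exp(beta_k * delta_std) - 1),   delta_std = delta_natural / sd_k

where ``delta_natural`` is the change on the predictor's own modelling scale
(log scale for logged covariates, so a doubling is delta = ln 2) and sd_k is
the fitted-sample standard deviation used in standardization (1 for the
unstandardized Econ/Single codes).  The posterior mean of the transformed
quantity is reported, not the transform of the posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CovariateStandardizer
from .sampler import PosteriorDraws


@dataclass(frozen=True)
class FirstDifference:
    predictor: str
    description: str
    mean_pct: float
    lo95_pct: float
    hi95_pct: float

    def __post_init__(self) -> None:
        # tolerance covers float noise when the posterior is a point mass
        slack = 1e-9 * max(1.0, abs(self.mean_pct))
        if not self.lo95_pct - slack <= self.mean_pct <= self.hi95_pct + slack:
            raise ValueError("interval must contain the mean")


def _beta_draws(draws, predictor: str) -> np.ndarray:
    frame = draws.draws if isinstance(draws, PosteriorDraws) else draws
    col = f"beta_{predictor}"
    if col not in frame.columns:
        slopes = [c[5:] for c in frame.columns if c.startswith("beta_")]
        raise ValueError(f"unknown predictor {predictor!r}; have {slopes}")
    return frame[col].to_numpy(dtype=float)


def first_difference(
    draws,
    predictor: str,
    delta_natural: float,
    standardizer: CovariateStandardizer | None = None,
    description: str | None = None,
) -> FirstDifference:
    """Posterior percent-change summary for one predictor change.

    ``draws`` is a PosteriorDraws or its frame; ``standardizer`` supplies the
    fitted sd for standardized continuous predictors (omit it for the
    unstandardized Econ/Single codes, whose effective sd is 1).
    """
    beta = _beta_draws(draws, predictor)
    sd_k = 1.0
    if standardizer is not None and predictor in getattr(standardizer, "columns", ()):
        sd_k = float(standardizer.sds_[predictor])
    if sd_k <= 0:
        raise ValueError(f"standard deviation for {predictor!r} must be positive")
    pct = 100.0 * np.expm1(beta * delta_natural / sd_k)
    lo, hi = np.percentile(pct, [2.5, 97.5])
    return FirstDifference(
        predictor=predictor,
        description=description or f"delta={delta_natural:g}",
        mean_pct=float(pct.mean()),
        lo95_pct=float(lo),
        hi95_pct=float(hi),
    )


def standard_first_differences(
    draws,
    standardizer: CovariateStandardizer,
    mean_doses: float,
) -> pd.DataFrame:
    """The canonical set of predictor changes reported for this model.

    +1 calendar year; +1 dose in the routine schedule (evaluated at the
    sample-mean schedule size, delta = ln((m+1)/m) on the log scale);
    doubling GDP per capita; doubling population; +1 percentage point of
    DTP3 coverage (+0.01 on the proportion scale).
    """
    specs = [
        ("year", 1.0, "+1 calendar year"),
        ("log_doses", float(np.log((mean_doses + 1.0) / mean_doses)), "+1 dose in schedule"),
        ("log_gdp", float(np.log(2.0)), "GDP per capita x2"),
        ("log_pop", float(np.log(2.0)), "population x2"),
        ("dtp3", 0.01, "+1 percentage point DTP3"),
    ]
    rows = []
    for pred, delta, desc in specs:
        fd = first_difference(draws, pred, delta, standardizer, desc)
        rows.append((fd.predictor, fd.description, fd.mean_pct, fd.lo95_pct, fd.hi95_pct))
    return pd.DataFrame(
        rows, columns=["predictor", "delta_description", "mean_pct", "lo95_pct", "hi95_pct"]
    )
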