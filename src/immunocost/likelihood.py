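"""Gamma log-link likelihood for category-decomposed cost-per-dose regression.

The observation model treats each cost-per-dose datum as the sum of the
category unit costs it covers.  Each of the four delivery cost categories
(labor, supply chain, other service delivery, capital) has its own intercept
on the log scale; all categories share one slope vector over the study- and
country-level predictors.  The expected total for observation *i* is

    tc_i = sum_l I_il * exp(b0_l + x_i . beta)

and the observed cost is Gamma distributed with shape ``alpha`` and rate
``alpha / tc_i``, i.e. mean ``tc_i`` and variance ``tc_i**2 / alpha``.

Priors: independent Normal(0, coef_sd) on every regression coefficient
(intercepts included) and half-Cauchy(scale=alpha_scale) on the shape.
The "noninformative" variant drops the coefficient priors (improper flat)
while keeping the half-Cauchy on the shape so the posterior stays proper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import digamma, gammaln

CATEGORIES: tuple[str, ...] = ("labor", "supply_chain", "service_delivery", "capital")

#: canonical slope order: Year, Econ, Single, log(Doses), DTP3, log(GDP), log(Pop)
DEFAULT_SLOPES: tuple[str, ...] = (
    "year",
    "econ",
    "single",
    "log_doses",
    "dtp3",
    "log_gdp",
    "log_pop",
)

PRIOR_VARIANTS = ("default", "weak", "noninformative")


@dataclass(frozen=True)
class PriorSpec:
    """Prior configuration for the meta-regression.

    coef_sd
        Standard deviation of the zero-centred normal prior shared by all
        regression coefficients.  1 for the informative baseline, 10 for the
        weakly informative sensitivity variant.
    alpha_scale
        Scale of the half-Cauchy prior on the Gamma shape parameter.
    variant
        "default", "weak" or "noninformative".  Under "noninformative" the
        coefficient priors are improper flat and ``coef_sd`` is ignored.
    """

    coef_sd: float = 1.0
    alpha_scale: float = 5.0
    variant: str = "default"

    def __post_init__(self) -> None:
        if self.coef_sd <= 0:
            raise ValueError(f"coef_sd must be positive, got {self.coef_sd}")
        if self.alpha_scale <= 0:
            raise ValueError(f"alpha_scale must be positive, got {self.alpha_scale}")
        if self.variant not in PRIOR_VARIANTS:
            raise ValueError(f"variant must be one of {PRIOR_VARIANTS}, got {self.variant!r}")

    @classmethod
    def from_variant(cls, variant: str, alpha_scale: float = 5.0) -> "PriorSpec":
        if variant == "weak":
            return cls(coef_sd=10.0, alpha_scale=alpha_scale, variant="weak")
        return cls(coef_sd=1.0, alpha_scale=alpha_scale, variant=variant)


@dataclass
class ModelParams:
    """One point in parameter space (numeric Econ coding, 12 parameters)."""

    intercept_labor: float = 0.0
    intercept_supply_chain: float = 0.0
    intercept_service_delivery: float = 0.0
    intercept_capital: float = 0.0
    beta_year: float = 0.0
    beta_econ: float = 0.0
    beta_single: float = 0.0
    beta_log_doses: float = 0.0
    beta_dtp3: float = 0.0
    beta_log_gdp: float = 0.0
    beta_log_pop: float = 0.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"Gamma shape alpha must be positive, got {self.alpha}")

    def intercepts(self) -> np.ndarray:
        return np.array(
            [getattr(self, f"intercept_{c}") for c in CATEGORIES], dtype=float
        )

    def slopes(self) -> np.ndarray:
        return np.array([getattr(self, f"beta_{s}") for s in DEFAULT_SLOPES], dtype=float)

    def to_vector(self) -> np.ndarray:
        """Stack as [4 intercepts, 7 slopes, alpha]."""
        return np.concatenate([self.intercepts(), self.slopes(), [self.alpha]])

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (12,):
            raise ValueError(f"expected a 12-vector, got shape {vec.shape}")
        names = param_names()
        return cls(**dict(zip(names, vec)))

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def param_names(slope_names: Sequence[str] = DEFAULT_SLOPES) -> list[str]:
    """Column order used everywhere draws are stored."""
    return (
        [f"intercept_{c}" for c in CATEGORIES]
        + [f"beta_{s}" for s in slope_names]
        + ["alpha"]
    )


def _slope_vector(x: Mapping[str, float] | Sequence[float],
                  slope_names: Sequence[str] = DEFAULT_SLOPES) -> np.ndarray:
    if isinstance(x, Mapping):
        return np.array([x[s] for s in slope_names], dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != (len(slope_names),):
        raise ValueError(
            f"covariate vector must have length {len(slope_names)}, got {x.shape}"
        )
    return x


def category_cost(params: ModelParams, x, category: str) -> float:
    """Expected cost per dose for one category at covariates ``x``.

    ``x`` is a mapping or sequence over the seven slopes in canonical order,
    already standardized with the fitted-sample moments.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    xv = _slope_vector(x)
    b0 = getattr(params, f"intercept_{category}")
    return float(np.exp(b0 + xv @ params.slopes()))


def total_cost(params: ModelParams, x, indicators) -> float:
    """Expected total cost per dose: sum of included category costs.

    ``indicators`` is a mapping over category names or a 4-sequence of
    booleans in canonical category order.  At least one must be set; a zero
    total would put the Gamma rate at infinity.
    """
    if isinstance(indicators, Mapping):
        inc = np.array([bool(indicators[c]) for c in CATEGORIES])
    else:
        inc = np.asarray(indicators, dtype=bool)
        if inc.shape != (4,):
            raise ValueError("indicators must have length 4")
    if not inc.any():
        raise ValueError("at least one cost-category indicator must be set")
    return float(sum(category_cost(params, x, c) for c, on in zip(CATEGORIES, inc) if on))


def total_cost_matrix(intercepts: np.ndarray, slopes: np.ndarray,
                      X: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Vectorized Eq-5 totals for n rows. X: (n,p), I: (n,4) boolean."""
    eta = X @ slopes  # (n,)
    with np.errstate(over="ignore"):
        cat = np.exp(eta[:, None] + intercepts[None, :])  # (n,4)
    return (cat * I).sum(axis=1)


def category_cost_matrix(intercepts: np.ndarray, slopes: np.ndarray,
                         X: np.ndarray) -> np.ndarray:
    """Per-category expected costs, shape (n, 4)."""
    eta = X @ slopes
    with np.errstate(over="ignore"):
        return np.exp(eta[:, None] + intercepts[None, :])


def gamma_log_density(y, alpha, mean):
    """Log density of Gamma(shape=alpha, rate=alpha/mean) at y.

    This is the shape-rate parameterization with E[y] = mean and
    Var[y] = mean**2 / alpha.  All arguments must be strictly positive;
    vectorized over y/mean.
    """
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    alpha = float(alpha)
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive (Gamma support)")
    if np.any(mean <= 0):
        raise ValueError("mean must be strictly positive")
    out = (
        alpha * (np.log(alpha) - np.log(mean))
        - gammaln(alpha)
        + (alpha - 1.0) * np.log(y)
        - alpha * y / mean
    )
    return out if out.ndim else float(out)


def _half_cauchy_logpdf(a: float, scale: float) -> float:
    return float(np.log(2.0) - np.log(np.pi * scale) - np.log1p((a / scale) ** 2))


def _coef_log_prior(coefs: np.ndarray, prior: PriorSpec) -> float:
    if prior.variant == "noninformative":
        return 0.0
    s = prior.coef_sd
    return float(
        -0.5 * np.sum((coefs / s) ** 2)
        - coefs.size * (np.log(s) + 0.5 * np.log(2 * np.pi))
    )


def log_prior(params: ModelParams, prior: PriorSpec) -> float:
    coefs = np.concatenate([params.intercepts(), params.slopes()])
    return _coef_log_prior(coefs, prior) + _half_cauchy_logpdf(params.alpha, prior.alpha_scale)


def log_posterior(params: ModelParams, y: np.ndarray, X: np.ndarray, I: np.ndarray,
                  prior: PriorSpec = PriorSpec()) -> float:
    """Unnormalized log posterior at ``params`` for a standardized dataset.

    Returns -inf (rather than raising) when alpha <= 0 or any expected
    total is non-positive, so samplers can reject such proposals.
    """
    if params.alpha <= 0:
        return -np.inf
    tc = total_cost_matrix(params.intercepts(), params.slopes(), X, I)
    if np.any(tc <= 0) or not np.all(np.isfinite(tc)):
        return -np.inf
    ll = float(np.sum(gamma_log_density(y, params.alpha, tc)))
    return ll + log_prior(params, prior)


def make_log_posterior(
    y: np.ndarray,
    X: np.ndarray,
    I: np.ndarray,
    prior: PriorSpec = PriorSpec(),
) -> tuple[Callable[[np.ndarray], float], Callable[[np.ndarray], np.ndarray]]:
    """Build (log_post, grad) over the unconstrained vector.

    Parameter layout: [4 intercepts, p slopes, log(alpha)].  The shape is
    sampled on the log scale; the log-Jacobian ``+log(alpha)`` is included so
    the density is over log(alpha).  The gradient is analytic (used for MAP
    optimisation and the Laplace proposal covariance).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    I = np.asarray(I, dtype=float)
    n, p = X.shape
    d = 4 + p + 1
    log_y_sum = float(np.sum(np.log(y)))
    scale = prior.alpha_scale
    flat = prior.variant == "noninformative"
    s2 = prior.coef_sd**2

    def _unpack(theta: np.ndarray):
        b0 = theta[:4]
        beta = theta[4 : 4 + p]
        alpha = np.exp(theta[-1])
        return b0, beta, alpha

    def logpost(theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        b0, beta, alpha = _unpack(theta)
        if not np.isfinite(alpha) or alpha <= 0:
            return -np.inf
        tc = total_cost_matrix(b0, beta, X, I)
        if np.any(tc <= 0) or not np.all(np.isfinite(tc)):
            return -np.inf
        log_tc = np.log(tc)
        ll = (
            n * (alpha * np.log(alpha) - gammaln(alpha))
            - alpha * np.sum(log_tc)
            + (alpha - 1.0) * log_y_sum
            - alpha * np.sum(y / tc)
        )
        lp = _half_cauchy_logpdf(alpha, scale) + theta[-1]  # + log-Jacobian
        if not flat:
            coefs = theta[:-1]
            lp += -0.5 * np.sum(coefs**2) / s2 - coefs.size * (
                np.log(prior.coef_sd) + 0.5 * np.log(2 * np.pi)
            )
        return float(ll + lp)

    def grad(theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        b0, beta, alpha = _unpack(theta)
        eta = X @ beta
        cat = np.exp(eta[:, None] + b0[None, :]) * I  # (n,4) included category costs
        tc = cat.sum(axis=1)
        resid = alpha * (y - tc) / tc**2  # d loglik / d tc, per row
        g = np.empty(d)
        g[:4] = cat.T @ resid
        g[4 : 4 + p] = X.T @ (resid * tc)
        dl_dalpha = (
            n * (np.log(alpha) + 1.0 - digamma(alpha))
            - np.sum(np.log(tc))
            + log_y_sum
            - np.sum(y / tc)
        )
        r2 = (alpha / scale) ** 2
        g[-1] = alpha * dl_dalpha - 2.0 * r2 / (1.0 + r2) + 1.0
        if not flat:
            g[:-1] -= theta[:-1] / s2
        return g

    return logpost, grad
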