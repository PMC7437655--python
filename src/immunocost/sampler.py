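"""Posterior sampling and convergence diagnostics.

The sampler is a self-contained adaptive random-walk Metropolis:

* the chain is initialised near the posterior mode (found by L-BFGS with the
  analytic gradient) and proposes from a multivariate normal whose covariance
  is the Laplace (inverse-Hessian) approximation at the mode;
* during burn-in the global proposal scale follows a Robbins-Monro recursion
  towards the 0.234 optimal acceptance rate, and halfway through burn-in the
  proposal covariance is refreshed from the empirical covariance of the
  burn-in draws (Haario-style); adaptation is frozen after burn-in so the
  retained draws come from a fixed-kernel Markov chain;
* chains are seeded independently via ``numpy.random.SeedSequence`` spawning,
  so runs are exactly reproducible for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when split-Rhat exceeds the tolerance."""


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration: 4 chains of 5000 iterations with the first
    2500 discarded, retaining 10,000 draws, unless overridden."""

    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for Rhat")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be in [0, iterations={self.iterations})"
            )

    @property
    def retained(self) -> int:
        return self.chains * (self.iterations - self.burn_in)


def adaptive_metropolis(
    log_prob: Callable[[np.ndarray], float],
    x0: np.ndarray,
    iterations: int,
    burn_in: int,
    rng: np.random.Generator,
    proposal_cov: np.ndarray | None = None,
    target_accept: float = 0.234,
) -> tuple[np.ndarray, dict]:
    """Run one adaptive random-walk Metropolis chain.

    Returns the ``iterations - burn_in`` retained draws and an info dict with
    the post-burn-in acceptance rate.
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    if proposal_cov is None:
        proposal_cov = np.eye(d)
    chol = np.linalg.cholesky(proposal_cov + 1e-12 * np.eye(d))
    log_scale = np.log(2.38 / np.sqrt(d))
    lp = log_prob(x)
    if not np.isfinite(lp):
        raise ValueError("log_prob is not finite at the initial point")

    n_keep = iterations - burn_in
    draws = np.empty((n_keep, d))
    burn_draws = np.empty((burn_in, d)) if burn_in else None
    accepted_post = 0
    refresh_at = burn_in // 2

    for t in range(iterations):
        step = np.exp(log_scale) * (chol @ rng.standard_normal(d))
        prop = x + step
        lp_prop = log_prob(prop)
        accept = np.log(rng.uniform()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
        if t < burn_in:
            burn_draws[t] = x
            # Robbins-Monro on the log proposal scale
            gamma = (t + 1) ** -0.6
            log_scale += gamma * ((1.0 if accept else 0.0) - target_accept)
            if t + 1 == refresh_at and refresh_at > max(10, 2 * d):
                emp = np.cov(burn_draws[:refresh_at].T)
                emp = np.atleast_2d(emp) + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(emp)
                except np.linalg.LinAlgError:
                    pass  # keep the Laplace proposal
        else:
            draws[t - burn_in] = x
            accepted_post += bool(accept)

    info = {"accept_rate": accepted_post / max(n_keep, 1), "final_scale": float(np.exp(log_scale))}
    return draws, info


def sample_chains(
    log_prob: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: SamplerConfig,
    proposal_cov: np.ndarray | None = None,
    jitter: float = 0.1,
) -> tuple[np.ndarray, dict]:
    """Run ``config.chains`` independent chains from jittered starts.

    Returns draws of shape (chains, iterations - burn_in, d) plus per-chain
    sampler info.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    if proposal_cov is None:
        proposal_cov = np.eye(d)
    sd = np.sqrt(np.diag(proposal_cov))
    seqs = np.random.SeedSequence(config.seed).spawn(config.chains)
    all_draws = np.empty((config.chains, config.iterations - config.burn_in, d))
    infos = []
    for c, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        start = x0 + jitter * sd * rng.standard_normal(d)
        if not np.isfinite(log_prob(start)):
            start = x0
        draws, info = adaptive_metropolis(
            log_prob, start, config.iterations, config.burn_in, rng, proposal_cov
        )
        all_draws[c] = draws
        infos.append(info)
    return all_draws, {"chains": infos}


def compute_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-Rhat (potential scale reduction factor) per parameter.

    ``chains`` has shape (m, n, d) — m chains of n retained draws.  Each
    chain is split in half, giving 2m sequences; Rhat compares between- and
    within-sequence variance.  Degenerate (zero-variance) parameters yield
    NaN with a warning rather than an error.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, d = chains.shape
    if m < 2:
        raise ValueError("Rhat requires at least 2 chains")
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split for Rhat")
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    ms, ns = split.shape[0], half
    means = split.mean(axis=1)            # (2m, d)
    varis = split.var(axis=1, ddof=1)     # (2m, d)
    W = varis.mean(axis=0)
    B = ns * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (ns - 1) / ns * W + B / ns
        rhat = np.sqrt(var_plus / W)
    zero = W <= 0
    if np.any(zero):
        warnings.warn(
            "zero within-chain variance for some parameters; Rhat undefined (NaN)",
            ConvergenceWarning,
        )
        rhat = np.where(zero, np.nan, rhat)
    return rhat


@dataclass
class PosteriorDraws:
    """Retained posterior draws stacked across chains.

    ``draws`` holds one row per retained draw with ``chain`` and ``iteration``
    bookkeeping columns followed by the parameter columns (intercepts, slopes,
    alpha — alpha on its natural, positive scale).
    """

    draws: pd.DataFrame
    param_names: list[str]
    rhat: pd.Series | None = None
    config: SamplerConfig | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("chain", "iteration", *self.param_names) if c not in self.draws]
        if missing:
            raise ValueError(f"draws frame missing columns: {missing}")
        if "alpha" in self.param_names and np.any(self.draws["alpha"].to_numpy() <= 0):
            raise ValueError("all retained draws must have alpha > 0")

    @property
    def n_retained(self) -> int:
        return len(self.draws)

    def parameter_array(self) -> np.ndarray:
        return self.draws[self.param_names].to_numpy()

    def by_chain(self) -> np.ndarray:
        """Reshape to (chains, n_per_chain, d) for diagnostics."""
        chains = sorted(self.draws["chain"].unique())
        per = [self.draws.loc[self.draws["chain"] == c, self.param_names].to_numpy() for c in chains]
        return np.stack(per)

    def summary(self) -> pd.DataFrame:
        arr = self.parameter_array()
        q = np.percentile(arr, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": arr.mean(axis=0),
                "sd": arr.std(axis=0, ddof=1),
                "lo95": q[0],
                "median": q[1],
                "hi95": q[2],
            },
            index=self.param_names,
        )

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)

    @classmethod
    def from_arrays(
        cls,
        chains_arr: np.ndarray,
        param_names: Sequence[str],
        config: SamplerConfig | None = None,
        info: dict | None = None,
    ) -> "PosteriorDraws":
        m, n, d = chains_arr.shape
        frame = pd.DataFrame(chains_arr.reshape(m * n, d), columns=list(param_names))
        frame.insert(0, "iteration", np.tile(np.arange(n), m))
        frame.insert(0, "chain", np.repeat(np.arange(m), n))
        rhat = pd.Series(compute_rhat(chains_arr), index=list(param_names))
        return cls(
            draws=frame,
            param_names=list(param_names),
            rhat=rhat,
            config=config,
            info=info or {},
        )
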