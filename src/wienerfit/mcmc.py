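"""Bayesian estimation of the four main diffusion parameters.

A random-walk Metropolis-within-Gibbs sampler targets the posterior under
independent uniform priors: each sweep updates ``a``, ``z_rel``, ``ter``
and ``v`` in turn with a Gaussian proposal, accepting by the Wiener
log-likelihood plus log-prior.  Proposal scales are tuned during a
discarded adaptation phase toward a 20-50 % acceptance rate.  Point
estimates are EAP (posterior means over the concatenated chains);
convergence is monitored with the Gelman-Rubin potential scale reduction
factor (PSRF), which compares between- and within-chain variance in an
ANOVA-like fashion and is ~1 at convergence.

Two prior presets are exposed.  ``"paper"`` restricts the drift prior to
``U(0, 1)``, which excludes negative drifts; ``"symmetric"`` widens it to
``U(-5, 5)`` so that recovery with negative true drifts is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .params import DMParams
from .simulate import Dataset
from .wiener import log_likelihood

__all__ = [
    "PriorSpec", "ChainConfig", "MCMCChains", "ChainDiagnostics",
    "run_mcmc", "eap", "psrf",
]

PARAM_NAMES = ("a", "z_rel", "ter", "v")


@dataclass
class PriorSpec:
    """Independent uniform priors, ``(low, high)`` per parameter."""

    a: tuple = (0.0001, 3.0)
    z_rel: tuple = (0.002, 0.998)
    ter: tuple = (0.0, 1.0)
    v: tuple = (0.0, 1.0)

    @classmethod
    def preset(cls, name: str) -> "PriorSpec":
        if name == "paper":
            return cls()
        if name == "symmetric":
            return cls(v=(-5.0, 5.0))
        raise ValueError(f"unknown prior preset {name!r}")

    def bounds(self) -> np.ndarray:
        return np.array([self.a, self.z_rel, self.ter, self.v])

    def midpoints(self) -> np.ndarray:
        b = self.bounds()
        return (b[:, 0] + b[:, 1]) / 2.0


@dataclass
class ChainConfig:
    """Chain scheme: three chains of 500 retained draws.

    Fixed per-chain starts follow the conventional scheme
    ``a = 1, 2, (floor)``, ``ter = 0.001``, ``v = 0.5, -0.5, 0``; a nominal
    start of ``a = 0`` is infeasible (outside any positive prior) and is
    clamped to the prior floor.  ``z_rel`` starts at 0.5 in every chain.
    ``burn_in`` adaptation sweeps are discarded before retention.
    """

    n_chains: int = 3
    n_samples: int = 500
    burn_in: int = 500
    initial_scales: tuple = (0.2, 0.1, 0.05, 0.2)

    def starts(self, priors: PriorSpec) -> np.ndarray:
        base = [
            [1.0, 0.5, 0.001, 0.5],
            [2.0, 0.5, 0.001, -0.5],
            [0.0, 0.5, 0.001, 0.0],
        ]
        bounds = priors.bounds()
        starts = []
        for i in range(self.n_chains):
            s = np.array(base[i % 3])
            s = np.clip(s, bounds[:, 0], bounds[:, 1])  # e.g. a=0 -> prior floor
            starts.append(s)
        return np.array(starts)


@dataclass
class MCMCChains:
    """Posterior draws, indexed chain x iteration x parameter."""

    draws: np.ndarray  # (n_chains, n_samples, 4), post burn-in
    acceptance: np.ndarray  # (n_chains, 4) acceptance rates in retention phase
    priors: PriorSpec = field(default_factory=PriorSpec)
    seed: Optional[int] = None
    failed: bool = False

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_samples(self) -> int:
        return self.draws.shape[1]

    def concatenated(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=list(PARAM_NAMES))
            df.insert(0, "iteration", np.arange(self.n_samples))
            df.insert(0, "chain", c)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass
class ChainDiagnostics:
    """Per-parameter PSRF point estimate and upper 95 % limit."""

    psrf: dict
    upper: dict
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"psrf": self.psrf, "upper": self.upper})


def _log_prior(x: np.ndarray, bounds: np.ndarray) -> float:
    if np.any(x < bounds[:, 0]) or np.any(x > bounds[:, 1]):
        return -np.inf
    return 0.0  # uniform: constant inside the support


def run_mcmc(data: Dataset, priors: Optional[PriorSpec] = None,
             config: Optional[ChainConfig] = None, seed: int = 0,
             use_likelihood: bool = True) -> MCMCChains:
    """Sample the posterior with Metropolis-within-Gibbs.

    ``use_likelihood=False`` samples the prior alone (a sampler
    correctness check: marginal means must approach prior midpoints).
    A chain in which every retained proposal is rejected marks the result
    as failed rather than raising.
    """
    priors = priors or PriorSpec()
    config = config or ChainConfig()
    bounds = priors.bounds()
    rng = np.random.default_rng(seed)

    def log_post(x: np.ndarray) -> float:
        lp = _log_prior(x, bounds)
        if not np.isfinite(lp) or not use_likelihood:
            return lp
        ll = log_likelihood(data, DMParams(a=x[0], z_rel=x[1], ter=x[2], v=x[3]))
        return lp + ll

    starts = config.starts(priors)
    all_draws = np.empty((config.n_chains, config.n_samples, 4))
    acc_rates = np.zeros((config.n_chains, 4))
    failed = False
    for c in range(config.n_chains):
        x = starts[c].copy()
        # ensure the start itself has positive prior density
        x = np.clip(x, bounds[:, 0] + 1e-12, bounds[:, 1] - 1e-12)
        lp = log_post(x)
        scales = np.array(config.initial_scales, dtype=float)
        acc_window = np.zeros(4)
        n_window = 0
        accepted = np.zeros(4)
        for it in range(config.burn_in + config.n_samples):
            adapting = it < config.burn_in
            for j in range(4):
                prop = x.copy()
                prop[j] += scales[j] * rng.standard_normal()
                lp_prop = log_post(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    if adapting:
                        acc_window[j] += 1
                    else:
                        accepted[j] += 1
            if adapting:
                n_window += 1
                if n_window == 25:  # adapt scales toward 20-50 % acceptance
                    rates = acc_window / n_window
                    scales[rates < 0.20] *= 0.7
                    scales[rates > 0.50] *= 1.4
                    acc_window[:] = 0.0
                    n_window = 0
            else:
                all_draws[c, it - config.burn_in] = x
        acc_rates[c] = accepted / config.n_samples
        if np.all(accepted == 0):
            failed = True
    return MCMCChains(draws=all_draws, acceptance=acc_rates, priors=priors,
                      seed=seed, failed=failed)


def eap(chains: MCMCChains) -> DMParams:
    """Expected-a-posteriori point estimate: mean of the concatenated draws."""
    flat = chains.concatenated()
    if flat.size == 0:
        raise ValueError("no retained draws")
    m = flat.mean(axis=0)
    return DMParams(a=float(m[0]), z_rel=float(m[1]), ter=float(m[2]), v=float(m[3]))


def psrf(chains: MCMCChains) -> ChainDiagnostics:
    """Gelman-Rubin potential scale reduction factor per parameter.

    Point estimate ``sqrt(((n-1)/n * W + (1 + 1/m) * B/n) / W)`` with ``W``
    the mean within-chain variance and ``B/n`` the variance of chain means;
    the upper limit inflates the between-chain component by the 97.5 %
    quantile of an F distribution (Brooks-Gelman style approximation).
    Zero-variance chains are flagged degenerate.
    """
    draws = chains.draws
    m, n, _ = draws.shape
    if m < 2 or n < 2:
        raise ValueError("PSRF needs at least 2 chains with 2 draws each")
    point, upper = {}, {}
    degenerate = False
    for j, name in enumerate(PARAM_NAMES):
        x = draws[:, :, j]
        chain_means = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        W = float(np.mean(s2))
        B_over_n = float(np.var(chain_means, ddof=1))
        if W <= 0:
            degenerate = True
            point[name] = np.nan
            upper[name] = np.nan
            continue
        ratio = (n - 1) / n + (1.0 + 1.0 / m) * B_over_n / W
        point[name] = float(np.sqrt(ratio))
        var_s2 = float(np.var(s2, ddof=1)) if m > 1 else 0.0
        df_w = 2.0 * W ** 2 / var_s2 if var_s2 > 0 else 1e6
        fq = float(f_dist.ppf(0.975, m - 1, df_w))
        upper[name] = float(np.sqrt((n - 1) / n + (1.0 + 1.0 / m) * fq * B_over_n / W))
    return ChainDiagnostics(psrf=point, upper=upper, degenerate=degenerate)
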