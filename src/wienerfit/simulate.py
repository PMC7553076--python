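"""Synthetic two-choice trial data: exact sampling, screening, summaries, I/O.

Trials are drawn exactly from the model: the boundary indicator from the
closed-form absorption probability, the response time by inverting the
conditional first-passage CDF (vectorized bisection on the defective CDF),
plus the non-decision offset.  The sampler is validated in the test suite
against an independent fine-step Euler random-walk simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .params import DMParams
from .wiener import fpt_cdf, prob_lower

__all__ = [
    "Dataset",
    "SummaryStats",
    "sample_trials",
    "screen_dataset",
    "summary_stats",
    "read_trials",
    "write_trials",
    "euler_sample_trials",
]


@dataclass
class Dataset:
    """A set of two-choice trials: boundary labels plus response times.

    ``responses`` holds 0 for lower- and 1 for upper-boundary crossings;
    ``rts`` the response times in seconds.  ``truth`` and ``seed`` record
    provenance when the data are synthetic.
    """

    responses: np.ndarray
    rts: np.ndarray
    truth: Optional[DMParams] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        self.rts = np.asarray(self.rts, dtype=float)
        if self.responses.shape != self.rts.shape or self.responses.ndim != 1:
            raise ValueError("responses and rts must be 1-d arrays of equal length")
        if self.n == 0:
            raise ValueError("a Dataset must contain at least one trial")
        if np.any(self.rts <= 0):
            raise ValueError("all response times must be positive")

    @property
    def n(self) -> int:
        return int(self.responses.size)

    @property
    def upper_mask(self) -> np.ndarray:
        return self.responses == 1

    @property
    def n_upper(self) -> int:
        return int(np.sum(self.responses == 1))

    @property
    def n_lower(self) -> int:
        return self.n - self.n_upper

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"response": self.responses, "rt": self.rts})


@dataclass
class SummaryStats:
    """Descriptive statistics of a dataset (overall and per boundary).

    Boundary-conditional means/variances are NaN when that boundary has too
    few trials (< 1 for the mean, < 2 for the unbiased sample variance).
    """

    p_up: float
    m_rt: float
    m_up: float
    m_lo: float
    v_rt: float
    v_up: float
    v_lo: float
    min_rt: float
    n: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("p_up", "m_rt", "m_up", "m_lo", "v_rt", "v_up", "v_lo", "min_rt", "n")}


def _invert_cdf(u: np.ndarray, boundary: str, params: DMParams,
                total_mass: float) -> np.ndarray:
    """Solve F_boundary(ter + t_dec) = u for decision time, vectorized."""
    if u.size == 0:
        return u.copy()
    # bracket: expand until the CDF exceeds every target
    hi = (params.a / params.s) ** 2 + 1.0
    for _ in range(200):
        reached = fpt_cdf(params.ter + hi, boundary, params)
        if reached >= min(total_mass, float(np.max(u))) or reached >= total_mass * (1 - 1e-12):
            if reached >= float(np.max(u)):
                break
        hi *= 2.0
    lo = np.zeros_like(u)
    hi_v = np.full_like(u, hi)
    for _ in range(70):
        mid = 0.5 * (lo + hi_v)
        below = fpt_cdf(params.ter + mid, boundary, params) < u
        lo = np.where(below, mid, lo)
        hi_v = np.where(below, hi_v, mid)
    return 0.5 * (lo + hi_v)


def sample_trials(params: DMParams, n: int, seed: int) -> Dataset:
    """Draw ``n`` iid trials exactly from the model.

    The boundary indicator follows the closed-form choice probability; the
    response time is ``ter`` plus a draw from the normalized conditional
    first-passage density, obtained by inverse-CDF sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p_lo = prob_lower(params)
    lower = rng.random(n) < p_lo
    rts = np.empty(n, dtype=float)
    u = rng.random(n)
    idx_lo = np.flatnonzero(lower)
    idx_up = np.flatnonzero(~lower)
    if idx_lo.size:
        targets = u[idx_lo] * p_lo
        rts[idx_lo] = params.ter + _invert_cdf(targets, "lower", params, p_lo)
    if idx_up.size:
        targets = u[idx_up] * (1.0 - p_lo)
        rts[idx_up] = params.ter + _invert_cdf(targets, "upper", params, 1.0 - p_lo)
    responses = (~lower).astype(int)
    return Dataset(responses=responses, rts=rts, truth=params, seed=seed)


def euler_sample_trials(params: DMParams, n: int, seed: int,
                        dt: float = 1e-4) -> Dataset:
    """Independent oracle sampler: fine-step Euler random walk.

    Approximate (bias of order ``sqrt(dt)``); used only for cross-validating
    the exact sampler, never in analysis code.
    """
    rng = np.random.default_rng(seed)
    a, z, v, s = params.a, params.z, params.v, params.s
    responses = np.empty(n, dtype=int)
    rts = np.empty(n, dtype=float)
    sqdt = np.sqrt(dt) * s
    block = 4096
    for i in range(n):
        x = z
        t = 0.0
        while True:
            steps = v * dt + sqdt * rng.standard_normal(block)
            path = x + np.cumsum(steps)
            hit = np.flatnonzero((path <= 0.0) | (path >= a))
            if hit.size:
                j = hit[0]
                responses[i] = 1 if path[j] >= a else 0
                rts[i] = params.ter + t + (j + 1) * dt
                break
            x = path[-1]
            t += block * dt
    return Dataset(responses=responses, rts=rts, truth=params, seed=seed)


def screen_dataset(data: Dataset, min_fraction: float = 0.04):
    """Flag datasets with fewer than ``min_fraction`` crossings at a boundary.

    Distance-based fitting is ill-defined when one boundary is (almost)
    never reached, so such datasets are marked problematic.
    Returns ``(problematic, n_lower, n_upper)``.
    """
    n_lo, n_up = data.n_lower, data.n_upper
    problematic = (n_lo < min_fraction * data.n) or (n_up < min_fraction * data.n)
    return problematic, n_lo, n_up


def summary_stats(data: Dataset) -> SummaryStats:
    """Boundary-conditional RT means and unbiased variances plus p_up."""
    rts = data.rts
    up = data.upper_mask
    def _mean(x):
        return float(np.mean(x)) if x.size >= 1 else float("nan")
    def _var(x):
        return float(np.var(x, ddof=1)) if x.size >= 2 else float("nan")
    return SummaryStats(
        p_up=float(np.mean(up)),
        m_rt=_mean(rts), m_up=_mean(rts[up]), m_lo=_mean(rts[~up]),
        v_rt=_var(rts), v_up=_var(rts[up]), v_lo=_var(rts[~up]),
        min_rt=float(np.min(rts)), n=data.n,
    )


def write_trials(data: Dataset, path, dialect: str = "csv") -> None:
    """Write trials as delimiter-separated text.

    ``csv``: header ``response,rt`` (0 = lower, 1 = upper).
    ``fast-dm``: two whitespace-separated columns RESPONSE TIME, no header.
    Times are written with 6 decimals, so round trips are lossless to 1e-6.
    """
    path = Path(path)
    df = data.to_frame()
    if dialect == "csv":
        df.to_csv(path, index=False, float_format="%.6f")
    elif dialect == "fast-dm":
        with open(path, "w") as fh:
            for resp, rt in zip(df["response"], df["rt"]):
                fh.write(f"{int(resp)} {rt:.6f}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_trials(path, dialect: str = "csv") -> Dataset:
    """Read trials written by :func:`write_trials` (or compatible files)."""
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        responses, rts = df["response"].to_numpy(), df["rt"].to_numpy()
    elif dialect == "fast-dm":
        df = pd.read_csv(path, sep=r"\s+", header=None, names=["response", "rt"])
        responses, rts = df["response"].to_numpy(), df["rt"].to_numpy()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return Dataset(responses=responses, rts=rts)
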