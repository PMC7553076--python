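"""Point estimation: EZ closed form, maximum likelihood, chi-square, K-S.

All iterative objectives are minimized over the four main parameters
``(a, z_rel, ter, v)`` in a transformed, unconstrained space::

    a     = exp(u1)            (positive)
    z_rel = sigmoid(u2)        (in (0,1))
    ter   = min_rt * sigmoid(u3)   (below the smallest observed RT)
    v     = u4                 (unrestricted)

The ``ter`` transform makes the classic failure mode — a non-decision-time
start above the fastest response, where the likelihood is identically
zero — impossible by construction; the conventional start ``ter0 = 0.001``
maps into the interior for any data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import approx_fprime, minimize
from scipy.special import expit, logit

from .params import DMParams
from .simulate import Dataset
from .wiener import deviance, fpt_cdf, prob_lower, prob_upper

__all__ = [
    "EZMoments", "StartingValues", "OptimizerSettings", "EstimationResult",
    "ez_moments", "ez_estimate", "ez_forward_moments",
    "cs_statistic", "cs_df", "build_super_curve", "ks_statistic", "ks_critical",
    "draw_starting_values", "fit",
]

ML_METHODS = {"ml-nm": "nelder-mead", "ml-bfgs": "bfgs", "ml-newton": "newton"}


# ---------------------------------------------------------------------------
# EZ: closed-form moment inversion (z_rel fixed at 0.5)
# ---------------------------------------------------------------------------

@dataclass
class EZMoments:
    """Moments consumed by the EZ inversion.

    ``pc`` is the proportion of upper-boundary responses ("correct" in this
    single-condition design means the upper boundary).  ``mrt``/``vrt`` are
    an RT mean and unbiased variance; see :func:`ez_moments` for the scope
    convention.
    """

    mrt: float
    vrt: float
    pc: float
    n: int
    degenerate: bool = False


def ez_moments(data: Dataset, scope: str = "all") -> EZMoments:
    """Choice proportion and RT moments feeding the EZ inversion.

    ``scope="all"`` (default) takes the RT mean/variance over every trial;
    ``scope="upper"`` restricts them to upper-boundary responses.  Under
    the EZ model's own assumption of an unbiased starting point the two are
    the same population quantity (the conditional RT distributions at both
    boundaries coincide when z = a/2), but on biased data they differ and
    drive different bias patterns.  The default is the behaviour of the
    common single-condition implementation, which hands the full RT vector
    to the moment step.
    """
    up = data.rts[data.upper_mask]
    pc = data.n_upper / data.n
    sel = data.rts if scope == "all" else up
    if scope not in ("all", "upper"):
        raise ValueError(f"unknown scope {scope!r}")
    degenerate = sel.size < 2 or (scope == "upper" and pc in (0.0, 1.0))
    mrt = float(np.mean(sel)) if sel.size else float("nan")
    vrt = float(np.var(sel, ddof=1)) if sel.size >= 2 else float("nan")
    return EZMoments(mrt=mrt, vrt=vrt, pc=pc, n=data.n, degenerate=degenerate)


def _ez_edge_correct(pc: float, n: int) -> float:
    """Replace the non-invertible proportions 0, 0.5, 1 by nudged values."""
    if pc == 0.0:
        return 1.0 / (2 * n)
    if pc == 1.0:
        return 1.0 - 1.0 / (2 * n)
    if pc == 0.5:
        return 0.5 + 1.0 / (2 * n)
    return pc


def ez_estimate(m: EZMoments, s_internal: float = 0.1) -> DMParams:
    """Closed-form EZ inversion of (mrt, vrt, pc) to (a, ter, v), z_rel = 0.5.

    Computed on the classic ``s = 0.1`` scale and then multiplied by 10 to
    the ``s = 1`` convention used everywhere else in the package.  The
    non-decision time may come out negative; that invalid-estimate pathway
    is deliberately preserved (it is itself an object of study).
    """
    if not np.isfinite(m.mrt) or not np.isfinite(m.vrt) or m.vrt <= 0:
        raise ValueError("EZ moments are degenerate beyond edge correction")
    pc = _ez_edge_correct(m.pc, m.n)
    if not (0.0 < pc < 1.0) or pc == 0.5:
        raise ValueError(f"proportion {pc} cannot be inverted")
    s = s_internal
    s2 = s * s
    L = logit(pc)
    x = L * (L * pc * pc - L * pc + pc - 0.5) / m.vrt
    v = np.sign(pc - 0.5) * s * x ** 0.25
    a = s2 * L / v
    y = -v * a / s2
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    ter = m.mrt - mdt
    factor = 1.0 / s  # rescale to the s = 1 convention
    # unchecked: the EZ non-decision time may legitimately come out negative
    return DMParams.unchecked(a=a * factor, z_rel=0.5, ter=ter, v=v * factor)


def ez_forward_moments(params: DMParams, method: str = "closed") -> EZMoments:
    """Population EZ moments for an unbiased (z_rel = 0.5) parameter set.

    ``closed`` evaluates the analytic mean/variance of the upper-boundary
    decision-time distribution; ``quadrature`` integrates the FPT density
    numerically.  The two agree to high precision and the test suite checks
    them against each other.
    """
    if params.z_rel != 0.5:
        raise ValueError("EZ forward moments require z_rel = 0.5")
    pc = prob_upper(params)
    if method == "closed":
        s2 = params.s ** 2
        a, v = params.a, params.v
        if abs(v) < 1e-7:
            # v -> 0 limits of the conditional FPT moments at z = a/2
            mdt = a * a / (4.0 * s2)
            vdt = a ** 4 / (24.0 * s2 * s2)
        else:
            y = -v * a / s2
            ey = np.exp(y)
            mdt = (a / (2.0 * v)) * (1.0 - ey) / (1.0 + ey)
            L = -y  # logit(pc) = v a / s^2
            vdt = s2 ** 2 * L * (L * pc * pc - L * pc + pc - 0.5) / v ** 4
        return EZMoments(mrt=params.ter + mdt, vrt=vdt, pc=pc, n=0)
    if method == "quadrature":
        def g(t):
            from .wiener import fpt_density
            return fpt_density(t + params.ter, "upper", params)
        norm, _ = quad(g, 0, np.inf, limit=400)
        m1, _ = quad(lambda t: t * g(t), 0, np.inf, limit=400)
        m2, _ = quad(lambda t: t * t * g(t), 0, np.inf, limit=400)
        mdt = m1 / norm
        vdt = m2 / norm - mdt ** 2
        return EZMoments(mrt=params.ter + mdt, vrt=vdt, pc=pc, n=0)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# CS: chi-square distance on RT-quantile bins
# ---------------------------------------------------------------------------

_CS_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
_CS_MIN_COUNT = 5  # below this a boundary collapses to a single bin


@dataclass
class CSBinning:
    """Quantile bin edges and observed counts, per boundary."""

    edges_lower: np.ndarray  # interior edges (may be empty if collapsed)
    edges_upper: np.ndarray
    obs_lower: np.ndarray
    obs_upper: np.ndarray

    @property
    def n_bins(self) -> int:
        return int(self.obs_lower.size + self.obs_upper.size)


def _bin_boundary(rts: np.ndarray):
    if rts.size < _CS_MIN_COUNT:
        return np.empty(0), np.array([float(rts.size)])
    edges = np.quantile(rts, _CS_QUANTILES)  # linear-interpolation quantiles
    # bins: (-inf, q10], (q10, q30], ..., (q90, inf) -> 6 bins
    counts = np.histogram(rts, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
    return edges, counts.astype(float)


def build_cs_binning(data: Dataset) -> CSBinning:
    """Observed counts in RT-quantile bins, separately per boundary.

    Each boundary with at least 5 responses contributes 6 bins cut at its
    0.1/0.3/0.5/0.7/0.9 sample quantiles; a sparser boundary collapses to a
    single bin holding all its trials.
    """
    lo = data.rts[~data.upper_mask]
    up = data.rts[data.upper_mask]
    e_lo, c_lo = _bin_boundary(lo)
    e_up, c_up = _bin_boundary(up)
    return CSBinning(edges_lower=e_lo, edges_upper=e_up,
                     obs_lower=c_lo, obs_upper=c_up)


def _expected_counts(edges: np.ndarray, boundary: str, params: DMParams,
                     n: int) -> np.ndarray:
    total_mass = prob_lower(params) if boundary == "lower" else prob_upper(params)
    if edges.size == 0:
        return np.array([n * total_mass])
    cdf_vals = fpt_cdf(edges, boundary, params)
    masses = np.diff(np.concatenate(([0.0], cdf_vals, [total_mass])))
    return n * np.maximum(masses, 0.0)


def cs_statistic(data: Dataset, params: DMParams,
                 binning: Optional[CSBinning] = None) -> float:
    """Pearson chi-square distance between observed and model bin counts."""
    if binning is None:
        binning = build_cs_binning(data)
    n = data.n
    stat = 0.0
    for edges, obs, boundary in (
            (binning.edges_lower, binning.obs_lower, "lower"),
            (binning.edges_upper, binning.obs_upper, "upper")):
        exp = _expected_counts(edges, boundary, params, n)
        exp = np.maximum(exp, 1e-10)
        stat += float(np.sum((obs - exp) ** 2 / exp))
    return stat


def cs_df(C: int, B: int, P: int) -> int:
    """Degrees of freedom ``C(B - 1) - P`` of the chi-square fit statistic.

    ``C`` experimental conditions, ``B`` bins across both distributions,
    ``P`` estimated parameters.  Warns when nonpositive.
    """
    if C <= 0 or B <= 0 or P <= 0:
        raise ValueError("C, B, P must be positive")
    df = C * (B - 1) - P
    if df <= 0:
        import warnings
        warnings.warn(f"nonpositive degrees of freedom: df = {df}")
    return df


# ---------------------------------------------------------------------------
# K-S: sup distance on the joined "super-curve"
# ---------------------------------------------------------------------------

@dataclass
class SuperCurve:
    """Joined empirical CDF over signed response times.

    Lower-boundary RTs are mirrored to the negative axis, so one curve
    represents both defective distributions contiguously; it crosses the
    origin at the proportion of lower responses.
    """

    signed_times: np.ndarray  # sorted jump locations
    heights: np.ndarray       # empirical CDF value at each jump (right-continuous)
    junction: float           # value approached at 0 = proportion lower


def build_super_curve(data: Dataset) -> SuperCurve:
    signed = np.where(data.upper_mask, data.rts, -data.rts)
    order = np.argsort(signed)
    signed = signed[order]
    heights = np.arange(1, data.n + 1, dtype=float) / data.n
    return SuperCurve(signed_times=signed, heights=heights,
                      junction=data.n_lower / data.n)


def _model_super_cdf(x: np.ndarray, params: DMParams) -> np.ndarray:
    """Model CDF on the signed-time axis."""
    x = np.asarray(x, dtype=float)
    p_lo = prob_lower(params)
    out = np.empty_like(x)
    neg = x < 0
    if np.any(neg):
        out[neg] = p_lo - fpt_cdf(-x[neg], "lower", params)
    if np.any(~neg):
        out[~neg] = p_lo + fpt_cdf(x[~neg], "upper", params)
    return out


def ks_statistic(data: Dataset, params: DMParams,
                 curve: Optional[SuperCurve] = None) -> float:
    """Sup distance between the empirical and model super-curves.

    Evaluated on both sides of every empirical jump, where the sup of the
    difference of a jump function and a continuous function is attained.
    """
    if curve is None:
        curve = build_super_curve(data)
    model = _model_super_cdf(curve.signed_times, params)
    upper_gap = np.abs(curve.heights - model)
    lower_gap = np.abs(np.concatenate(([0.0], curve.heights[:-1])) - model)
    return float(np.max(np.maximum(upper_gap, lower_gap)))


def ks_critical(alpha: float) -> float:
    """Asymptotic K-S critical value ``sqrt(log(2/alpha)/2)``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.sqrt(np.log(2.0 / alpha) / 2.0))


# ---------------------------------------------------------------------------
# Fitting harness
# ---------------------------------------------------------------------------

@dataclass
class StartingValues:
    """Random starting values: a0, z0, v0 ~ U(0.2, 0.8); ter0 fixed at 0.001."""

    a0: float
    z0: float
    v0: float
    ter0: float = 0.001


def draw_starting_values(rng: np.random.Generator) -> StartingValues:
    a0, z0, v0 = rng.uniform(0.2, 0.8, size=3)
    return StartingValues(a0=a0, z0=z0, v0=v0)


@dataclass
class OptimizerSettings:
    """Search configuration for the iterative fits."""

    algorithm: str = "nelder-mead"  # nelder-mead | bfgs | newton
    max_iterations: int = 5000
    fd_step: float = 1e-4  # finite-difference step for the gradient-based fits
    xtol: float = 1e-6
    ftol: float = 1e-8


@dataclass
class EstimationResult:
    """One method's point estimates with convergence metadata."""

    method: str
    params_hat: Optional[DMParams]
    objective_value: float
    converged: bool
    iterations: int
    start: Optional[StartingValues] = None
    wall_time: float = 0.0
    message: str = ""

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "objective_value": self.objective_value,
            "converged": self.converged,
            "iterations": self.iterations,
            "wall_time": self.wall_time,
            "message": self.message,
        }
        if self.params_hat is not None:
            d.update(a=self.params_hat.a, z_rel=self.params_hat.z_rel,
                     ter=self.params_hat.ter, v=self.params_hat.v)
        if self.start is not None:
            d.update(a0=self.start.a0, z0=self.start.z0,
                     v0=self.start.v0, ter0=self.start.ter0)
        return d


# search box for the raw-space simplex fits
_BOX_LO = np.array([0.05, 0.01, 0.0, -10.0])
_BOX_HI = np.array([10.0, 0.99, np.inf, 10.0])


def _to_unconstrained(p: DMParams, min_rt: float) -> np.ndarray:
    frac = np.clip(p.ter / min_rt, 1e-9, 1 - 1e-9)
    return np.array([np.log(p.a), logit(p.z_rel), logit(frac), p.v])


def _from_unconstrained(u: np.ndarray, min_rt: float) -> DMParams:
    return DMParams(a=float(np.exp(np.clip(u[0], -20, 20))),
                    z_rel=float(expit(np.clip(u[1], -35, 35))),
                    ter=float(min_rt * expit(np.clip(u[2], -35, 35))),
                    v=float(np.clip(u[3], -50, 50)))


def _nelder_mead_raw(raw_objective, x0: np.ndarray, min_rt: float,
                     settings: OptimizerSettings):
    """Simplex search in raw parameter space with a box penalty.

    The initial simplex is scaled to the data: the non-decision-time vertex
    reaches most of the way to the fastest response, so a conventional
    start at 0.001 s cannot strand the search on a flat region.  One
    restart from the first solution guards against premature collapse.
    """
    hi = np.array([10.0, 0.99, min_rt * (1 - 1e-6), 10.0])

    def fun(x):
        if np.any(x < _BOX_LO) or np.any(x > hi):
            return 1e6 + float(np.sum(np.abs(x)))  # sloped penalty wall
        return raw_objective(DMParams(*x))

    steps = np.array([0.8, 0.3, 0.8 * (min_rt - x0[2]), 1.0])
    simplex = [x0] + [np.clip(x0 + np.eye(4)[i] * steps[i], _BOX_LO, hi)
                      for i in range(4)]
    opts = {"maxiter": settings.max_iterations,
            "xatol": settings.xtol, "fatol": settings.ftol}
    res = minimize(fun, x0, method="Nelder-Mead",
                   options={**opts, "initial_simplex": np.array(simplex)})
    total_iter = res.nit
    res2 = minimize(fun, res.x, method="Nelder-Mead", options=opts)
    total_iter = min(total_iter + res2.nit, settings.max_iterations)
    best = res2 if res2.fun <= res.fun else res
    return best.x, float(best.fun), int(total_iter), bool(best.success or res.success)


def fit(data: Dataset, objective: str = "ml",
        optimizer: Optional[OptimizerSettings] = None,
        start: Optional[StartingValues] = None,
        seed: Optional[int] = None) -> EstimationResult:
    """Minimize the deviance (``ml``), chi-square (``cs``) or K-S (``ks``)
    objective over ``(a, z_rel, ter, v)``, or apply the closed form (``ez``).

    The simplex fits search raw parameter space inside a penalty box; the
    gradient-based ML variants (BFGS with finite-difference step 1e-4 and
    the Newton-type search) work in a smooth unconstrained transform where
    ``ter`` is a logit fraction of the smallest observed RT.  On a
    non-finite objective at the start, fresh starting values are drawn (up
    to 20 times) and the redraw is noted in the result message.  Optimizer
    failure yields an unconverged result, never an exception.
    """
    optimizer = optimizer or OptimizerSettings()
    t0 = time.perf_counter()

    if objective == "ez":
        try:
            est = ez_estimate(ez_moments(data))
            return EstimationResult("ez", est, objective_value=float("nan"),
                                    converged=True, iterations=0, start=None,
                                    wall_time=time.perf_counter() - t0)
        except ValueError as exc:
            return EstimationResult("ez", None, float("nan"), False, 0,
                                    wall_time=time.perf_counter() - t0,
                                    message=str(exc))

    min_rt = float(np.min(data.rts))
    if objective == "ml":
        def raw_objective(p: DMParams) -> float:
            val = deviance(data, p)
            return val if np.isfinite(val) else 1e10
    elif objective == "cs":
        binning = build_cs_binning(data)
        def raw_objective(p: DMParams) -> float:
            return cs_statistic(data, p, binning=binning)
    elif objective == "ks":
        curve = build_super_curve(data)
        def raw_objective(p: DMParams) -> float:
            return ks_statistic(data, p, curve=curve)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    rng = np.random.default_rng(seed)
    if start is None:
        start = draw_starting_values(rng)
    message = ""
    for attempt in range(20):
        x0_raw = np.array([start.a0, float(np.clip(start.z0, 0.02, 0.98)),
                           min(start.ter0, 0.999 * min_rt), start.v0])
        if np.isfinite(raw_objective(DMParams(*x0_raw))) and raw_objective(DMParams(*x0_raw)) < 1e9:
            break
        message = f"redrew starting values ({attempt + 1}x); "
        start = draw_starting_values(rng)

    alg = optimizer.algorithm
    label = objective if objective in ("cs", "ks") else \
        f"ml-{'nm' if alg == 'nelder-mead' else alg}"
    try:
        if alg == "nelder-mead" or objective in ("cs", "ks"):
            x_hat, f_hat, n_iter, converged = _nelder_mead_raw(
                raw_objective, x0_raw, min_rt, optimizer)
            params_hat = DMParams(*x_hat)
        else:
            def fun(u: np.ndarray) -> float:
                return raw_objective(_from_unconstrained(u, min_rt))
            u0 = _to_unconstrained(DMParams(*x0_raw), min_rt)
            if alg == "bfgs":
                res = minimize(fun, u0, method="BFGS",
                               options={"maxiter": optimizer.max_iterations,
                                        "eps": optimizer.fd_step, "gtol": 1e-5})
                # status 2 = line-search precision loss at the optimum
                converged = bool(res.success) or res.status == 2
            elif alg == "newton":
                jac = lambda u: approx_fprime(u, fun, 1e-6)
                res = minimize(fun, u0, method="Newton-CG", jac=jac,
                               options={"maxiter": optimizer.max_iterations,
                                        "xtol": optimizer.xtol})
                # status 3 (inner CG stall on a non-PD Hessian) still ends at
                # a stationary point; accept it when the gradient is flat
                converged = bool(res.success) or (
                    res.status == 3 and np.isfinite(res.fun)
                    and float(np.max(np.abs(jac(res.x)))) < 1e-3 * (1 + abs(res.fun)))
            else:
                raise ValueError(f"unknown algorithm {alg!r}")
            x_hat, f_hat, n_iter = res.x, float(res.fun), int(res.nit)
            params_hat = _from_unconstrained(x_hat, min_rt)
    except Exception as exc:
        return EstimationResult(label, None, float("inf"), False, 0, start,
                                time.perf_counter() - t0, message + str(exc))
    return EstimationResult(label, params_hat, float(f_hat), converged,
                            int(n_iter), start, time.perf_counter() - t0, message)
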