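"""Exact evaluation of Wiener diffusion first-passage quantities.

Implements, for a Wiener process with drift ``v`` and scale ``s`` between
absorbing boundaries 0 and ``a`` started at ``z = z_rel * a``:

* the probability of absorption at the lower boundary (closed form),
* the defective first-passage-time (FPT) density at either boundary,
* the defective FPT distribution function, and
* the trial-level log-likelihood / deviance.

The FPT density has two classical series representations: a "large-time"
sine series and a "small-time" sum over mirror images.  Each is truncated
to an absolute tolerance (default ``1e-10`` per evaluation, on the
time-normalized density) and the representation needing fewer terms is
selected per evaluation point, following the standard term-count bounds of
Navarro & Fuss (2009).  The distribution function uses a closed-form
image expansion in terms of Gaussian CDFs for small normalized times and
the term-wise integral of the sine series otherwise.

Upper-boundary quantities follow from the reflection ``v -> -v``,
``z -> a - z``.  All quantities are zero for ``t <= ter``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

from .params import DMParams

__all__ = [
    "prob_lower",
    "prob_upper",
    "fpt_density",
    "fpt_cdf",
    "log_likelihood",
    "deviance",
    "DEFAULT_TOL",
]

#: absolute truncation tolerance per series evaluation
DEFAULT_TOL = 1e-10

# switch point between the image-expansion CDF and the sine-series CDF,
# in units of normalized time  t_dec / (a/s)^2
_CDF_TAU_SWITCH = 2.0


def _check_boundary(boundary: str) -> None:
    if boundary not in ("lower", "upper"):
        raise ValueError(f"boundary must be 'lower' or 'upper', got {boundary!r}")


def prob_lower(params: DMParams) -> float:
    """Probability that the process is absorbed at the lower boundary.

    Continuous at ``v = 0`` where the limit ``1 - z/a`` applies.
    """
    a, z = params.a / params.s, params.z / params.s
    v = params.v / params.s
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return 1.0 - z / a
    if v > 0:
        # exponents negative: (e^{-2va} - e^{-2vz}) / (e^{-2va} - 1)
        return (np.exp(-x) - np.exp(-2.0 * v * z)) / np.expm1(-x)
    # v < 0: multiply through by e^{2va} so exponents stay negative
    return np.expm1(2.0 * v * (a - z)) / np.expm1(x)


def prob_upper(params: DMParams) -> float:
    """Probability of absorption at the upper boundary, ``1 - P(lower)``."""
    return prob_lower(params.reflected())


def _f0_small(tau: np.ndarray, w: float, tol: float) -> np.ndarray:
    """Image-expansion (small-time) normalized density f0(tau, w)."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    if tau.size == 0:
        return out
    # Navarro-Fuss term count for the small-time series
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 2.0 * np.sqrt(2.0 * np.pi * tau) * tol
        ks = np.where(arg < 1.0,
                      2.0 + np.sqrt(np.maximum(-2.0 * tau * np.log(np.maximum(arg, 1e-300)), 0.0)),
                      2.0)
    ks = np.maximum(ks, np.sqrt(tau) + 1.0)
    kmax = int(np.ceil(np.max(ks) / 2.0)) + 1
    k = np.arange(-kmax, kmax + 1)[:, None]
    c = w + 2.0 * k
    out = np.sum(c * np.exp(-c * c / (2.0 * tau[None, :])), axis=0)
    return out / np.sqrt(2.0 * np.pi * tau ** 3)


def _f0_large(tau: np.ndarray, w: float, tol: float) -> np.ndarray:
    """Sine-series (large-time) normalized density f0(tau, w)."""
    tau = np.asarray(tau, dtype=float)
    if tau.size == 0:
        return np.zeros_like(tau)
    tmin = float(np.min(tau))
    # need k pi e^{-k^2 pi^2 tau / 2} < tol
    kl = np.sqrt(max(-2.0 * np.log(max(np.pi * tmin * tol, 1e-300)), 0.0)
                 / (np.pi ** 2 * tmin))
    kmax = max(int(np.ceil(kl)), int(np.ceil(1.0 / (np.pi * np.sqrt(tmin)))), 1) + 1
    k = np.arange(1, kmax + 1)[:, None]
    series = np.sum(k * np.sin(k * np.pi * w)
                    * np.exp(-k * k * np.pi ** 2 * tau[None, :] / 2.0), axis=0)
    return np.pi * series


def _small_time_cheaper(tau: np.ndarray, tol: float) -> np.ndarray:
    """Mask of points where the image expansion needs fewer terms."""
    tau = np.asarray(tau, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 2.0 * np.sqrt(2.0 * np.pi * tau) * tol
        ks = np.where(arg < 1.0,
                      2.0 + np.sqrt(np.maximum(-2.0 * tau * np.log(np.maximum(arg, 1e-300)), 0.0)),
                      2.0)
        ks = np.maximum(ks, np.sqrt(tau) + 1.0)
        la = np.pi * tau * tol
        kl = np.where(la < 1.0,
                      np.sqrt(np.maximum(-2.0 * np.log(np.maximum(la, 1e-300)), 0.0)
                              / (np.pi ** 2 * tau)),
                      1.0 / (np.pi * np.sqrt(tau)))
    return ks < kl


def _density_lower(t_dec: np.ndarray, params: DMParams, tol: float) -> np.ndarray:
    """Defective FPT density at the lower boundary vs decision time ``t_dec``."""
    a = params.a / params.s
    v = params.v / params.s
    w = params.z_rel
    t_dec = np.asarray(t_dec, dtype=float)
    out = np.zeros_like(t_dec)
    pos = t_dec > 0
    if not np.any(pos):
        return out
    tp = t_dec[pos]
    tau = tp / a ** 2
    f0 = np.empty_like(tau)
    small = _small_time_cheaper(tau, tol)
    f0[small] = _f0_small(tau[small], w, tol)
    f0[~small] = _f0_large(tau[~small], w, tol)
    f0 = np.maximum(f0, 0.0)
    # assemble in log space so extreme drifts cannot overflow
    with np.errstate(divide="ignore"):
        log_dens = np.log(f0) - 2.0 * np.log(a) - v * a * w - v * v * tp / 2.0
    out[pos] = np.exp(np.clip(log_dens, -745.0, 700.0)) * (f0 > 0)
    return out


def fpt_density(t, boundary: str, params: DMParams, tol: float = DEFAULT_TOL):
    """Defective first-passage-time density at ``boundary``, vs clock time ``t``.

    The density refers to the observed response time (decision time plus
    ``ter``) and integrates over ``t`` to that boundary's absorption
    probability.  It is exactly zero for ``t <= ter``.
    """
    _check_boundary(boundary)
    p = params if boundary == "lower" else params.reflected()
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    out = _density_lower(np.atleast_1d(t) - p.ter, p, tol)
    return float(out[0]) if scalar else out


def _cdf_small(t_dec: np.ndarray, a: float, z: float, v: float, tol: float) -> np.ndarray:
    """Image-expansion lower-boundary defective CDF (s = 1 units)."""
    t = np.asarray(t_dec, dtype=float)
    tmax = float(np.max(t))
    span = np.sqrt(max(2.0 * tmax * np.log(1.0 / tol), 0.0)) + z + abs(v) * tmax
    kmax = min(int(np.ceil(span / (2.0 * a))) + 1, 200)
    sqt = np.sqrt(t)

    def _piece(c: float) -> np.ndarray:
        # integral_0^t  c/sqrt(2 pi u^3) exp(-v z - v^2 u/2 - c^2/(2u)) du
        t1 = np.exp(v * (c - z) + log_ndtr(-(c + v * t) / sqt))
        t2 = np.exp(-v * (c + z) + log_ndtr((v * t - c) / sqt))
        return t1 + t2

    out = np.zeros_like(t)
    for k in range(0, kmax + 1):
        out += _piece(2.0 * k * a + z)
    for m in range(1, kmax + 1):
        out -= _piece(2.0 * m * a - z)
    return np.clip(out, 0.0, 1.0)


def _cdf_large(t_dec: np.ndarray, a: float, z: float, v: float,
               p_lower: float, tol: float) -> np.ndarray:
    """Term-wise-integrated sine-series lower-boundary defective CDF (s = 1)."""
    t = np.asarray(t_dec, dtype=float)
    tmin = float(np.min(t))
    tau = tmin / a ** 2
    kl = np.sqrt(max(-2.0 * np.log(max(tol * tau, 1e-300)), 0.0) / (np.pi ** 2 * tau))
    kmax = max(int(np.ceil(kl)), 2) + 1
    k = np.arange(1, kmax + 1)[:, None]
    lam = (v * v + k * k * np.pi ** 2 / a ** 2) / 2.0
    tail = np.sum(k * np.sin(k * np.pi * z / a) / lam * np.exp(-lam * t[None, :]), axis=0)
    out = p_lower - np.pi / a ** 2 * np.exp(-z * v) * tail
    return np.clip(out, 0.0, 1.0)


def fpt_cdf(t, boundary: str, params: DMParams, tol: float = DEFAULT_TOL):
    """Defective FPT distribution function at ``boundary`` vs clock time ``t``.

    Nondecreasing in ``t``; 0 for ``t <= ter``; tends to the boundary's
    absorption probability as ``t -> infinity``.
    """
    _check_boundary(boundary)
    p = params if boundary == "lower" else params.reflected()
    a = p.a / p.s
    z = p.z / p.s
    v = p.v / p.s
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t_dec = np.atleast_1d(t) - p.ter
    out = np.zeros_like(t_dec)
    pos = t_dec > 0
    if np.any(pos):
        tp = t_dec[pos]
        tau = tp / a ** 2
        res = np.empty_like(tp)
        small = tau <= _CDF_TAU_SWITCH
        if np.any(small):
            res[small] = _cdf_small(tp[small], a, z, v, tol)
        if np.any(~small):
            res[~small] = _cdf_large(tp[~small], a, z, v, prob_lower(p), tol)
        out[pos] = res
    return float(out[0]) if scalar else out


_LOG_FLOOR = np.log(1e-300)


def log_likelihood(data, params: DMParams, tol: float = DEFAULT_TOL) -> float:
    """Summed log FPT density over the trials of ``data``.

    Returns ``-inf`` whenever any trial has ``rt <= ter`` (the density is
    identically zero there, which is why gradient-based estimation needs a
    constrained parameterization).  Densities that underflow are floored at
    1e-300 before the log so finite data never produce NaN.
    """
    rts = np.asarray(data.rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty dataset")
    if np.any(rts <= params.ter):
        return -np.inf
    upper = np.asarray(data.upper_mask, dtype=bool)
    total = 0.0
    for boundary, mask in (("lower", ~upper), ("upper", upper)):
        if np.any(mask):
            dens = fpt_density(rts[mask], boundary, params, tol=tol)
            total += float(np.sum(np.maximum(np.log(np.maximum(dens, 1e-300)), _LOG_FLOOR)))
    return total


def deviance(data, params: DMParams, tol: float = DEFAULT_TOL) -> float:
    """``-2 * log_likelihood`` — the quantity minimized by the ML fits."""
    return -2.0 * log_likelihood(data, params, tol=tol)
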