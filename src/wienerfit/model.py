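"""Model/results interface for fitting the diffusion model to trial data.

``WienerModel`` wraps a :class:`~wienerfit.simulate.Dataset` and exposes
``fit`` (EZ / maximum likelihood / chi-square / Kolmogorov-Smirnov) and
``fit_bayes`` (MCMC).  Point fits return a :class:`WienerFitResults`
carrying estimates, standard errors where available, convergence metadata
and a ``summary()`` table; Bayesian fits return
:class:`BayesianWienerResults` with posterior draws, EAP estimates,
posterior SDs and Gelman-Rubin diagnostics.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import estimators as est
from . import mcmc as mc
from .params import DMParams
from .simulate import Dataset, read_trials, summary_stats
from .wiener import deviance, fpt_density, log_likelihood

__all__ = ["WienerModel", "WienerFitResults", "BayesianWienerResults"]

PARAM_INDEX = ["a", "z_rel", "ter", "v"]

FIT_METHODS = ("ez", "ml-nm", "ml-bfgs", "ml-newton", "cs", "ks")

_ALGO = {"ml-nm": "nelder-mead", "ml-bfgs": "bfgs", "ml-newton": "newton"}


class WienerModel:
    """Four-parameter Wiener diffusion model for one set of two-choice trials."""

    def __init__(self, data: Dataset):
        self.data = data

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "response",
                       rt: str = "rt") -> "WienerModel":
        """Build from a DataFrame with a 0/1 response column and RTs in seconds."""
        return cls(Dataset(responses=df[response].to_numpy(),
                           rts=df[rt].to_numpy()))

    @classmethod
    def from_csv(cls, path, dialect: str = "csv") -> "WienerModel":
        return cls(read_trials(path, dialect=dialect))

    # -- likelihood ---------------------------------------------------------
    def loglike(self, params: DMParams) -> float:
        return log_likelihood(self.data, params)

    def deviance(self, params: DMParams) -> float:
        return deviance(self.data, params)

    # -- fitting ------------------------------------------------------------
    def fit(self, method: str = "ml-nm",
            start: Optional[est.StartingValues] = None,
            settings: Optional[est.OptimizerSettings] = None,
            seed: Optional[int] = None) -> "WienerFitResults":
        """Fit by one of ``ez, ml-nm, ml-bfgs, ml-newton, cs, ks``."""
        if method not in FIT_METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {FIT_METHODS}")
        if method == "ez":
            res = est.fit(self.data, "ez")
        elif method in _ALGO:
            settings = settings or est.OptimizerSettings(algorithm=_ALGO[method])
            settings.algorithm = _ALGO[method]
            res = est.fit(self.data, "ml", settings, start, seed)
        else:
            res = est.fit(self.data, method, settings, start, seed)
        return WienerFitResults(self, res)

    def fit_bayes(self, prior_preset: str = "symmetric",
                  priors: Optional[mc.PriorSpec] = None,
                  config: Optional[mc.ChainConfig] = None,
                  seed: int = 0) -> "BayesianWienerResults":
        """Posterior sampling with Metropolis-within-Gibbs; EAP point estimates."""
        priors = priors or mc.PriorSpec.preset(prior_preset)
        chains = mc.run_mcmc(self.data, priors, config, seed=seed)
        return BayesianWienerResults(self, chains)


class WienerFitResults:
    """Point-estimation results with convergence metadata.

    ``bse`` holds observed-information standard errors for the ML fits
    (finite-difference Hessian of the log-likelihood at the optimum) and
    NaN for the distance-based and closed-form methods, whose sampling
    variability has no comparable plug-in estimate.
    """

    def __init__(self, model: WienerModel, result: est.EstimationResult):
        self.model = model
        self.raw_result = result
        self.method = result.method
        self.converged = result.converged
        self.objective_value = result.objective_value
        self.iterations = result.iterations
        self.params_hat = result.params_hat
        if result.params_hat is not None:
            self.params = pd.Series(result.params_hat.as_tuple(), index=PARAM_INDEX)
        else:
            self.params = pd.Series(np.nan, index=PARAM_INDEX)
        self.bse = self._standard_errors()

    def _standard_errors(self) -> pd.Series:
        if not self.method.startswith("ml") or self.params_hat is None:
            return pd.Series(np.nan, index=PARAM_INDEX)
        x0 = np.array(self.params_hat.as_tuple())
        h = 1e-4 * np.maximum(np.abs(x0), 1e-2)

        def nll(x):
            try:
                val = -log_likelihood(self.model.data,
                                      DMParams(a=x[0], z_rel=x[1], ter=x[2], v=x[3]))
            except Exception:
                return np.inf
            return val

        H = np.empty((4, 4))
        f0 = nll(x0)
        for i in range(4):
            xp = x0.copy(); xp[i] += h[i]
            xm = x0.copy(); xm[i] -= h[i]
            H[i, i] = (nll(xp) - 2 * f0 + nll(xm)) / h[i] ** 2
            for j in range(i + 1, 4):
                xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (nll(xpp) - nll(xpm) - nll(xmp) + nll(xmm)) / (4 * h[i] * h[j])
        try:
            if not np.all(np.isfinite(H)):
                raise np.linalg.LinAlgError
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(4, np.nan)
        return pd.Series(se, index=PARAM_INDEX)

    def summary(self) -> str:
        data = self.model.data
        lines = [
            "Wiener diffusion model fit",
            "=" * 46,
            f"Method:        {self.method}",
            f"Trials:        {data.n} ({data.n_upper} upper / {data.n_lower} lower)",
            f"Converged:     {self.converged}   iterations: {self.iterations}",
            f"Objective:     {self.objective_value:.6g}",
            "-" * 46,
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for name in PARAM_INDEX:
            se = self.bse[name]
            se_str = f"{se:12.4f}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:>8} {self.params[name]:12.4f} {se_str}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_fit(self, ax=None, n_grid: int = 200):
        """Overlay the fitted FPT densities on RT histograms (upper positive,
        lower mirrored negative), the conventional diffusion-model display."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        p = self.params_hat
        t = np.linspace(1e-3, float(data.rts.max()) * 1.2, n_grid)
        up = data.rts[data.upper_mask]
        lo = data.rts[~data.upper_mask]
        if up.size:
            ax.hist(up, bins=30, density=True,
                    weights=np.full(up.size, up.size / data.n),
                    alpha=0.4, color="tab:green", label="upper (observed)")
        if lo.size:
            ax.hist(-lo, bins=30, density=True,
                    weights=np.full(lo.size, lo.size / data.n),
                    alpha=0.4, color="tab:red", label="lower (observed)")
        if p is not None:
            ax.plot(t, fpt_density(t, "upper", p), color="tab:green")
            ax.plot(-t, fpt_density(t, "lower", p), color="tab:red")
        ax.set_xlabel("signed response time (s)")
        ax.set_ylabel("defective density")
        ax.legend()
        return ax


class BayesianWienerResults:
    """Posterior-sampling results: draws, EAP, posterior SDs, diagnostics."""

    def __init__(self, model: WienerModel, chains: mc.MCMCChains):
        self.model = model
        self.chains = chains
        self.failed = chains.failed
        flat = chains.concatenated()
        self.params = pd.Series(flat.mean(axis=0), index=PARAM_INDEX)
        self.bse = pd.Series(flat.std(axis=0, ddof=1), index=PARAM_INDEX)
        self.params_hat = mc.eap(chains)
        self.diagnostics = mc.psrf(chains)

    @property
    def method(self) -> str:
        return "bayes"

    @property
    def converged(self) -> bool:
        return (not self.failed) and all(
            np.isfinite(v) and v < 1.2 for v in self.diagnostics.psrf.values())

    def summary(self) -> str:
        ch = self.chains
        lines = [
            "Wiener diffusion model - Bayesian fit (EAP)",
            "=" * 58,
            f"Chains:        {ch.n_chains} x {ch.n_samples} retained draws",
            f"Failed:        {self.failed}",
            "-" * 58,
            f"{'param':>8} {'EAP':>10} {'post. SD':>10} {'PSRF':>8} {'upper':>8}",
        ]
        for name in PARAM_INDEX:
            lines.append(
                f"{name:>8} {self.params[name]:10.4f} {self.bse[name]:10.4f} "
                f"{self.diagnostics.psrf[name]:8.3f} {self.diagnostics.upper[name]:8.3f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_trace(self, axes=None):
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 8))
        for j, name in enumerate(PARAM_INDEX):
            for c in range(self.chains.n_chains):
                axes[j].plot(self.chains.draws[c, :, j], lw=0.6)
            axes[j].set_ylabel(name)
        axes[-1].set_xlabel("iteration")
        return axes
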