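"""Model / Results interface for the SV-TVP-FAVAR.

Usage follows the familiar fit-object pattern::

    from svtvpfavar import SVTVPFAVAR

    model = SVTVPFAVAR.from_dataframe(
        df, panel_cols=panel, core_cols=["gdp", "health_exp"], epu_col="epu",
        k=3, p=2,
    )
    res = model.fit(n_draws=3000, n_burn=1000, thin=2, seed=7)
    print(res.summary())
    surface = res.irf(H=12)              # responses to the EPU shock
    slice_2020 = surface.slice_at("2020Q1")

The model object holds the (already stationary, standardized) data and the
prior; ``fit`` runs the Gibbs sampler and returns a results object that
carries the retained posterior draws, convergence diagnostics and the
impulse-response machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import ConvergenceReport, posterior_summary
from .factors import extract_factors_pca, select_num_factors
from .gibbs import ModelDims, PosteriorDraws, PriorConfig, SamplerConfig, run_gibbs
from .irf import IRFSurface, irf_surface_from_draws

__all__ = ["SVTVPFAVAR", "SVTVPFAVARResults"]


class SVTVPFAVAR:
    """Factor-augmented VAR with time-varying parameters and stochastic volatility.

    Parameters
    ----------
    core : (T, l) array or DataFrame
        Core observed variables z_t; by convention the last column is the
        target (expenditure) series.
    epu : (T,) array or Series
        The uncertainty index m_t (the shock variable, ordered last).
    panel : (T, n) array or DataFrame, optional
        High-dimensional standardized indicator panel from which k common
        factors are extracted (PCA in two-step mode; re-sampled as latent
        states in joint mode).
    factors : (T, k) array, optional
        Pre-computed factors; mutually exclusive with ``panel``.
    k : int or None
        Number of common factors; None selects it with the Bai-Ng ICp2
        criterion (k_max=8).
    p, q : int
        VAR lag order and idiosyncratic AR order.
    mode : 'two_step' | 'joint'
    priors : PriorConfig, optional; defaults to the Minnesota prior.

    Inputs are assumed stationary and standardized (see
    :func:`svtvpfavar.preprocess.preprocess_panel`).
    """

    def __init__(
        self,
        core,
        epu,
        panel=None,
        factors=None,
        k: int | None = 3,
        p: int = 2,
        q: int = 1,
        mode: str = "two_step",
        priors: PriorConfig | None = None,
        quarters=None,
    ):
        if (panel is None) == (factors is None):
            raise ValueError("provide exactly one of panel= or factors=")
        self.core = pd.DataFrame(core)
        self.epu = pd.Series(np.asarray(epu, float).ravel(), name=getattr(epu, "name", "epu") or "epu")
        self.panel = None if panel is None else pd.DataFrame(panel)
        self.mode = mode
        self.p = p
        self.q = q
        self.priors = priors
        self.quarters = quarters
        if factors is not None:
            factors = np.asarray(factors, float)
            self.k = factors.shape[1]
            self._factors = factors
        else:
            X = self.panel.to_numpy(float)
            if k is None:
                k = select_num_factors(X, k_max=min(8, min(X.shape) - 1))
            self.k = k
            self._factors, self._pca_loadings = extract_factors_pca(X, k)
        self.l = self.core.shape[1]
        T = len(self.core)
        if not (len(self.epu) == T == len(self._factors)):
            raise ValueError("core, epu, panel/factors must share the same T")
        self.dims = ModelDims(
            k=self.k,
            l=self.l,
            p=p,
            q=q,
            n=0 if self.panel is None else self.panel.shape[1],
            T=T,
        )
        self.var_names = (
            [f"f{j + 1}" for j in range(self.k)]
            + [str(c) for c in self.core.columns]
            + [str(self.epu.name)]
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        panel_cols: list[str],
        core_cols: list[str],
        epu_col: str,
        quarter_col: str | None = "quarter",
        **kwargs,
    ) -> "SVTVPFAVAR":
        """Build the model from one wide DataFrame with column roles."""
        quarters = None
        if quarter_col is not None and quarter_col in df.columns:
            quarters = df[quarter_col].astype(str).tolist()
        return cls(
            core=df[core_cols],
            epu=df[epu_col],
            panel=df[panel_cols],
            quarters=quarters,
            **kwargs,
        )

    @property
    def y(self) -> np.ndarray:
        """(T, m) augmented vector [factors, core, epu]."""
        return np.hstack(
            [self._factors, self.core.to_numpy(float), self.epu.to_numpy()[:, None]]
        )

    def fit(
        self,
        n_draws: int = 10_000,
        n_burn: int = 2_000,
        thin: int = 5,
        seed: int = 0,
        time_varying_b: bool = True,
        time_varying_a: bool = True,
        time_varying_s: bool = True,
    ) -> "SVTVPFAVARResults":
        """Run the Gibbs sampler and return a results object."""
        sampler = SamplerConfig(
            n_draws=n_draws,
            n_burn=n_burn,
            thin=thin,
            seed=seed,
            mode=self.mode,
            time_varying_b=time_varying_b,
            time_varying_a=time_varying_a,
            time_varying_s=time_varying_s,
        )
        priors = self.priors or PriorConfig.minnesota(self.y, self.dims)
        times = (
            list(self.quarters[self.p :])
            if self.quarters is not None
            else None
        )
        draws = run_gibbs(
            self.y,
            self.dims,
            priors=priors,
            sampler=sampler,
            panel=None if self.panel is None else self.panel.to_numpy(float),
            var_names=self.var_names,
            times=times,
        )
        return SVTVPFAVARResults(self, draws, sampler, priors)


class SVTVPFAVARResults:
    """Posterior draws plus diagnostics and impulse-response accessors."""

    def __init__(self, model, draws: PosteriorDraws, sampler, priors):
        self.model = model
        self.draws = draws
        self.sampler = sampler
        self.priors = priors
        self._convergence: ConvergenceReport | None = None

    @property
    def n_retained(self) -> int:
        return self.draws.n_retained

    def posterior_summary(self, quantiles=(0.05, 0.5, 0.95)):
        return posterior_summary(self.draws, quantiles)

    def convergence(self) -> ConvergenceReport:
        if self._convergence is None:
            self._convergence = ConvergenceReport.from_draws(self.draws)
        return self._convergence

    def irf(
        self,
        shock: int | str | None = None,
        H: int = 12,
        quantiles=(0.05, 0.5, 0.95),
        shock_size: str = "one_sd",
        keep_draws: bool = False,
    ) -> IRFSurface:
        """Time-varying impulse-response surface to ``shock`` (default: EPU)."""
        if shock is None:
            shock = self.draws.dims.m - 1
        elif isinstance(shock, str):
            shock = self.model.var_names.index(shock)
        return irf_surface_from_draws(
            self.draws,
            shock_var=shock,
            H=H,
            quantiles=quantiles,
            shock_size=shock_size,
            times=self.draws.times,
            variable_names=self.model.var_names,
            keep_draws=keep_draws,
        )

    def summary(self) -> str:
        """Readable run summary: dimensions, priors, volatility profile, diagnostics."""
        d = self.draws.dims
        lines = [
            "SV-TVP-FAVAR results",
            "=" * 60,
            f"variables (m):        {d.m}  = {d.k} factors + {d.l} core + EPU",
            f"VAR lag order p:      {d.p}",
            f"effective sample T:   {self.draws.b_path.shape[1]}",
            f"retained draws:       {self.n_retained} "
            f"(of {self.sampler.n_draws}, burn {self.sampler.n_burn}, thin {self.sampler.thin})",
            f"mode:                 {self.sampler.mode}",
            "",
            "posterior mean shock volatilities (time average):",
        ]
        sig = self.draws.sigma_path.mean(axis=(0, 1))
        names = self.model.var_names
        for j in range(d.m):
            lines.append(f"  sigma[{names[j]:>12s}]  {sig[j]:8.4f}")
        rep = self.convergence()
        lines.append("")
        lines.append("convergence (Geweke z / inefficiency factor):")
        for name in rep.geweke:
            lines.append(
                f"  {name:>12s}  z = {rep.geweke[name]:7.2f}   "
                f"IF = {rep.inefficiency[name]:7.2f}"
            )
        if rep.flags:
            lines.append("flags: " + "; ".join(rep.flags))
        return "\n".join(lines)

    def save(self, path) -> None:
        self.draws.save_hdf5(path)
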