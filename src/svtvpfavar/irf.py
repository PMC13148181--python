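"""Time-varying impulse responses to an uncertainty shock.

Shocks are identified recursively: the reduced-form covariance is
Omega_t = A_t^{-1} S_t S_t' A_t^{-1}' with A_t unit-diagonal lower
triangular and S_t = diag(sigma_1t, ..., sigma_mt), so with the augmented
vector ordered [factors, core observables, EPU index] the EPU innovation is
the last orthogonalized shock.  Responses at each date t freeze the VAR
coefficients and the impact matrix at their time-t values (the standard
TVP-VAR convention) and propagate through the companion form:

    response_h = J C_t^h J' (A_t^{-1} S_t) e_shock * scale.

Surfaces stack these paths over shock dates and posterior draws; bands are
pointwise posterior quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImpactMatrix",
    "IRFSlice",
    "IRFSurface",
    "build_companion",
    "structural_impact",
    "irf_path_at_time",
    "irf_surface_from_paths",
    "irf_surface_from_draws",
    "export_surface",
    "load_surface",
]


def build_companion(b_t: np.ndarray, m: int, p: int) -> np.ndarray:
    """Companion matrix of a VAR(p) from the stacked coefficient vector.

    ``b_t`` stacks vec(b_1t), ..., vec(b_pt) (column-major vec), length
    m^2 p.  The top block row holds [b_1t ... b_pt]; sub-diagonal identity
    blocks shift the lags.
    """
    b_t = np.asarray(b_t, float).ravel()
    if b_t.size != m * m * p:
        raise ValueError(f"coefficient vector length {b_t.size} != m^2 p = {m * m * p}")
    C = np.zeros((m * p, m * p))
    for lag in range(p):
        blk = b_t[lag * m * m : (lag + 1) * m * m].reshape((m, m), order="F")
        C[:m, lag * m : (lag + 1) * m] = blk
    if p > 1:
        C[m:, : m * (p - 1)] = np.eye(m * (p - 1))
    return C


def alpha_to_lower_triangular(alpha_t: np.ndarray, m: int) -> np.ndarray:
    """Unit-diagonal lower-triangular A_t from the stacked free elements.

    Free elements are ordered row by row: (2,1), (3,1), (3,2), (4,1), ...
    """
    alpha_t = np.asarray(alpha_t, float).ravel()
    expected = m * (m - 1) // 2
    if alpha_t.size != expected:
        raise ValueError(f"alpha length {alpha_t.size} != m(m-1)/2 = {expected}")
    A = np.eye(m)
    pos = 0
    for i in range(1, m):
        A[i, :i] = alpha_t[pos : pos + i]
        pos += i
    return A


@dataclass
class ImpactMatrix:
    """Contemporaneous structural impact A_t^{-1} S_t at one date."""

    matrix: np.ndarray

    @property
    def omega(self) -> np.ndarray:
        """Implied reduced-form covariance (A^{-1} S)(A^{-1} S)'."""
        return self.matrix @ self.matrix.T


def structural_impact(alpha_t: np.ndarray, sigma_t: np.ndarray) -> ImpactMatrix:
    """The lower-triangular impact A_t^{-1} S_t of the recursive identification."""
    sigma_t = np.asarray(sigma_t, float).ravel()
    if np.any(sigma_t <= 0.0):
        raise ValueError("shock standard deviations must be strictly positive")
    m = sigma_t.size
    A = alpha_to_lower_triangular(alpha_t, m)
    impact = np.linalg.solve(A, np.diag(sigma_t))
    return ImpactMatrix(impact)


def irf_path_at_time(
    b_t: np.ndarray,
    alpha_t: np.ndarray,
    sigma_t: np.ndarray,
    shock_var: int,
    H: int,
    m: int,
    p: int,
    shock_size: str = "one_sd",
) -> np.ndarray:
    """(H+1, m) response path to a shock in variable ``shock_var`` at one date.

    ``shock_size='one_sd'`` scales by the shock equation's own standard
    deviation (responses then inherit stochastic volatility);
    ``'unit'`` normalizes the structural shock's impact on its own variable
    to one.
    """
    impact = structural_impact(alpha_t, sigma_t).matrix
    col = impact[:, shock_var].copy()
    if shock_size == "unit":
        col = col / impact[shock_var, shock_var]
    elif shock_size != "one_sd":
        raise ValueError("shock_size must be 'one_sd' or 'unit'")
    C = build_companion(b_t, m, p)
    out = np.empty((H + 1, m))
    state = np.zeros(m * p)
    state[:m] = col
    out[0] = state[:m]
    for h in range(1, H + 1):
        state = C @ state
        out[h] = state[:m]
    return out


def _surface_from_paths(b, alpha, sigma, shock_var, H, m, p, shock_size):
    T = b.shape[0]
    out = np.empty((T, H + 1, m))
    for t in range(T):
        out[t] = irf_path_at_time(
            b[t], alpha[t], sigma[t], shock_var, H, m, p, shock_size
        )
    return out


def irf_surface_from_paths(
    b_path: np.ndarray,
    alpha_path: np.ndarray,
    sigma_path: np.ndarray,
    shock_var: int,
    H: int,
    m: int,
    p: int,
    shock_size: str = "one_sd",
) -> np.ndarray:
    """(T, H+1, m) deterministic response surface from one set of paths.

    Used both for ground-truth surfaces in simulations and per-draw inside
    :func:`irf_surface_from_draws`.
    """
    return _surface_from_paths(
        np.asarray(b_path, float),
        np.asarray(alpha_path, float),
        np.asarray(sigma_path, float),
        shock_var,
        H,
        m,
        p,
        shock_size,
    )


@dataclass
class IRFSlice:
    """Per-horizon median and band of the response at one shock date."""

    quarter: str
    horizons: np.ndarray
    variable_names: list[str]
    q05: np.ndarray  # (H+1, m)
    q50: np.ndarray
    q95: np.ndarray

    def response(self, variable: int | str):
        j = (
            self.variable_names.index(variable)
            if isinstance(variable, str)
            else variable
        )
        return self.q05[:, j], self.q50[:, j], self.q95[:, j]


@dataclass
class IRFSurface:
    """Posterior-quantile surface of responses: shock date x horizon x variable."""

    times: list[str]
    horizons: np.ndarray
    variable_names: list[str]
    q05: np.ndarray  # (T, H+1, m)
    q50: np.ndarray
    q95: np.ndarray
    shock_variable: int = -1
    shock_size: str = "one_sd"
    draws: np.ndarray | None = field(default=None, repr=False)

    def slice_at(self, quarter: str | int) -> IRFSlice:
        t = self.times.index(quarter) if isinstance(quarter, str) else quarter
        return IRFSlice(
            quarter=self.times[t],
            horizons=self.horizons,
            variable_names=self.variable_names,
            q05=self.q05[t],
            q50=self.q50[t],
            q95=self.q95[t],
        )

    def plot_slice(self, quarter, variable, ax=None):
        """Convenience band plot of one response path (non-normative)."""
        import matplotlib.pyplot as plt

        sl = self.slice_at(quarter)
        lo, med, hi = sl.response(variable)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(sl.horizons, lo, hi, alpha=0.3, label="90% band")
        ax.plot(sl.horizons, med, label="median")
        ax.axhline(0.0, lw=0.5, color="k")
        ax.set_xlabel("horizon (quarters)")
        ax.set_title(f"response of {variable} at {sl.quarter}")
        ax.legend()
        return ax


def irf_surface_from_draws(
    draws,
    shock_var: int,
    H: int,
    quantiles=(0.05, 0.5, 0.95),
    shock_size: str = "one_sd",
    times: list[str] | None = None,
    variable_names: list[str] | None = None,
    keep_draws: bool = False,
) -> IRFSurface:
    """Pointwise-quantile IRF surface over retained posterior draws.

    ``draws`` is a :class:`~svtvpfavar.gibbs.PosteriorDraws`; per draw and
    per shock date the response path is computed with coefficients frozen at
    that date, then 5/50/95 percent quantiles are taken cell-wise.
    """
    b = draws.b_path
    alpha = draws.alpha_path
    sigma = draws.sigma_path
    ndraw, T, _ = b.shape
    if ndraw < 1:
        raise ValueError("no retained draws")
    m, p = draws.dims.m, draws.dims.p
    if shock_var < 0:
        shock_var = m + shock_var
    surfaces = np.empty((ndraw, T, H + 1, m))
    for d in range(ndraw):
        surfaces[d] = _surface_from_paths(
            b[d], alpha[d], sigma[d], shock_var, H, m, p, shock_size
        )
    qs = np.quantile(surfaces, quantiles, axis=0)
    if times is None:
        times = [str(t) for t in range(T)]
    if variable_names is None:
        variable_names = [f"var{j}" for j in range(m)]
    return IRFSurface(
        times=list(times),
        horizons=np.arange(H + 1),
        variable_names=list(variable_names),
        q05=qs[0],
        q50=qs[1],
        q95=qs[2],
        shock_variable=shock_var,
        shock_size=shock_size,
        draws=surfaces if keep_draws else None,
    )


def export_surface(surface: IRFSurface, path) -> None:
    """Write a surface as long-format CSV: quarter,horizon,variable,q05,q50,q95."""
    rows = []
    T = len(surface.times)
    for t in range(T):
        for hi, h in enumerate(surface.horizons):
            for j, name in enumerate(surface.variable_names):
                rows.append(
                    (
                        surface.times[t],
                        int(h),
                        name,
                        surface.q05[t, hi, j],
                        surface.q50[t, hi, j],
                        surface.q95[t, hi, j],
                    )
                )
    df = pd.DataFrame(
        rows, columns=["quarter", "horizon", "variable", "q05", "q50", "q95"]
    )
    df.to_csv(path, index=False, float_format="%.12g")


def load_surface(path) -> IRFSurface:
    """Read back a surface written by :func:`export_surface`."""
    df = pd.read_csv(path)
    times = list(dict.fromkeys(df["quarter"].astype(str)))
    horizons = np.array(sorted(df["horizon"].unique()))
    names = list(dict.fromkeys(df["variable"].astype(str)))
    shape = (len(times), len(horizons), len(names))
    q05 = np.full(shape, np.nan)
    q50 = np.full(shape, np.nan)
    q95 = np.full(shape, np.nan)
    t_ix = {q: i for i, q in enumerate(times)}
    h_ix = {h: i for i, h in enumerate(horizons)}
    v_ix = {v: i for i, v in enumerate(names)}
    for row in df.itertuples(index=False):
        t, h, v = t_ix[str(row.quarter)], h_ix[row.horizon], v_ix[str(row.variable)]
        q05[t, h, v] = row.q05
        q50[t, h, v] = row.q50
        q95[t, h, v] = row.q95
    return IRFSurface(
        times=times,
        horizons=horizons,
        variable_names=names,
        q05=q05,
        q50=q50,
        q95=q95,
    )
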