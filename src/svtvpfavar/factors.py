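"""Common-factor block: principal-component extraction, factor-number
selection, and the Gibbs updates of the factor-equation parameters.

The observation (factor) equation for panel series i is

    x_it = lf_i' f_t + lz_i' z_t + lm_i m_t + u_it,
    u_it = rho_i1 u_it-1 + ... + rho_iq u_it-q + e_it,
    e_it ~ N(0, exp(2 h_it)),

with latent common factors f_t, core observables z_t and the uncertainty
index m_t.  Factors are identified by unit sample variance plus a sign
convention (the loading of largest magnitude on each factor is positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .statespace import RandomWalkBlockLaw, sample_sv_ksc

__all__ = [
    "FactorLoadings",
    "IdiosyncraticModel",
    "extract_factors_pca",
    "select_num_factors",
    "sample_loadings",
    "sample_idio_ar",
    "sample_idio_sv",
]


@dataclass
class FactorLoadings:
    """Loadings of the panel on factors, core observables and the EPU index."""

    lambda_f: np.ndarray  # (n, k)
    lambda_z: np.ndarray  # (n, l)
    lambda_m: np.ndarray  # (n, 1)

    @property
    def full(self) -> np.ndarray:
        """(n, k+l+1) concatenated loading matrix in [f, z, m] order."""
        return np.hstack([self.lambda_f, self.lambda_z, self.lambda_m])


@dataclass
class IdiosyncraticModel:
    """AR(q) + stochastic-volatility model of the idiosyncratic errors."""

    rho: np.ndarray  # (n, q)
    h_path: np.ndarray  # (T, n) log-volatilities
    q_h: float = 0.01  # innovation variance of the h random walks


def _sign_normalize(factors: np.ndarray, loadings: np.ndarray):
    """Flip each factor so its largest-magnitude loading is positive."""
    for j in range(factors.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            factors[:, j] *= -1.0
            loadings[:, j] *= -1.0
    return factors, loadings


def extract_factors_pca(panel: np.ndarray, k: int):
    """First k principal components of a standardized panel.

    Factors are variance-ordered, normalized to unit sample variance
    (ddof=1) and sign-normalized; loadings are the least-squares regression
    of each series on the factors.

    Returns ``(factors (T, k), loadings (n, k))``.
    """
    X = np.asarray(panel, float)
    T, n = X.shape
    if k < 1 or k > min(T, n):
        raise ValueError(f"k={k} outside 1..min(T, n)={min(T, n)}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    f = U[:, :k] * s[:k]
    f = f - f.mean(axis=0)
    f = f / f.std(axis=0, ddof=1)
    lam, *_ = np.linalg.lstsq(f, X, rcond=None)
    f, lam_T = _sign_normalize(f, lam.T)
    return f, lam_T


def select_num_factors(panel: np.ndarray, k_max: int = 8) -> int:
    """Number of common factors by the Bai-Ng ICp2 information criterion.

    ICp2(k) = log V(k) + k * (n+T)/(nT) * log min(n, T), with V(k) the mean
    squared residual after removing the first k principal components; the
    minimizer over 1..k_max is returned.
    """
    X = np.asarray(panel, float)
    T, n = X.shape
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > min(T, n):
        raise ValueError(f"k_max={k_max} exceeds min(T, n)={min(T, n)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    penalty = (n + T) / (n * T) * np.log(min(n, T))
    # numerically-exact low rank: once the residual is at rounding-error
    # scale, extra factors fit noise of the arithmetic, not of the data
    v_floor = (total / (n * T)) * 1e-10
    best_k, best_ic = 1, np.inf
    for k in range(1, k_max + 1):
        ssr = total - (s[:k] ** 2).sum()
        v = max(ssr / (n * T), 1e-300)
        if v <= v_floor:
            return k
        ic = np.log(v) + k * penalty
        if ic < best_ic:
            best_ic, best_k = ic, k
    return best_k


def _quasi_difference(y: np.ndarray, rho: np.ndarray):
    """Apply the AR filter (1 - rho_1 L - ... - rho_q L^q) along axis 0.

    Drops the first q rows (no pre-sample values are imputed).
    """
    q = len(rho)
    if q == 0:
        return y
    out = y[q:].astype(float).copy()
    for j in range(1, q + 1):
        out -= rho[j - 1] * y[q - j : len(y) - j]
    return out


def sample_loadings(
    panel: np.ndarray,
    factors: np.ndarray,
    core: np.ndarray,
    epu: np.ndarray,
    idio: IdiosyncraticModel,
    prior_var: float,
    rng: np.random.Generator,
) -> FactorLoadings:
    """Conjugate Gaussian draw of all per-series loadings.

    Each series' regression on W_t = [f_t, z_t, m_t] is quasi-differenced by
    its AR polynomial and variance-weighted by exp(-2 h_it) so the error is
    i.i.d.; the posterior is then standard Bayes linear
    regression with an N(0, prior_var I) prior.  ``prior_var = 0`` is read
    as an infinite-precision prior and returns the prior mean (zeros).
    """
    X = np.asarray(panel, float)
    W = np.hstack(
        [
            np.asarray(factors, float),
            np.atleast_2d(np.asarray(core, float).reshape(len(X), -1)),
            np.asarray(epu, float).reshape(-1, 1),
        ]
    )
    T, n = X.shape
    k = np.asarray(factors).shape[1]
    l = W.shape[1] - k - 1
    nreg = W.shape[1]
    lam = np.zeros((n, nreg))
    if prior_var <= 0.0:
        return FactorLoadings(lam[:, :k], lam[:, k : k + l], lam[:, -1:])
    prior_prec = 1.0 / prior_var
    for i in range(n):
        rho_i = idio.rho[i] if idio.rho.size else np.empty(0)
        xi = _quasi_difference(X[:, i], rho_i)
        Wi = _quasi_difference(W, rho_i)
        hi = idio.h_path[len(idio.h_path) - len(xi) :, i]
        wts = np.exp(-2.0 * hi)  # error variance is exp(2 h)
        Ww = Wi * wts[:, None]
        prec = prior_prec * np.eye(nreg) + Ww.T @ Wi
        prec = 0.5 * (prec + prec.T)
        try:
            L = np.linalg.cholesky(prec)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular posterior precision for series index {i}"
            ) from exc
        mean = np.linalg.solve(prec, Ww.T @ xi)
        z = rng.standard_normal(nreg)
        lam[i] = mean + np.linalg.solve(L.T, z)
    return FactorLoadings(lam[:, :k], lam[:, k : k + l], lam[:, -1:])


def _ar_stable(rho: np.ndarray) -> bool:
    """True when the AR polynomial 1 - rho_1 z - ... has roots outside the unit circle."""
    q = len(rho)
    if q == 0:
        return True
    companion = np.zeros((q, q))
    companion[0] = rho
    if q > 1:
        companion[1:, :-1] = np.eye(q - 1)
    return bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1.0)


def sample_idio_ar(
    u: np.ndarray,
    q: int,
    h_path: np.ndarray,
    rng: np.random.Generator,
    prior_var: float = 1.0,
    stability: bool = True,
    max_tries: int = 100,
) -> np.ndarray:
    """Conjugate draw of one series' idiosyncratic AR(q) coefficients.

    The AR regression of u_t on its own lags is weighted by exp(-h_t) to
    account for heteroskedastic errors.  With ``stability`` the draw is
    rejection-sampled to roots outside the unit circle.
    """
    if q == 0:
        return np.empty(0)
    u = np.asarray(u, float).ravel()
    T = u.size
    if T <= q + 2:
        raise ValueError(f"need T > q + 2, got T={T}, q={q}")
    if prior_var <= 0.0:
        return np.zeros(q)
    y = u[q:]
    Xl = np.column_stack([u[q - j : T - j] for j in range(1, q + 1)])
    h = np.asarray(h_path, float).ravel()[-len(y) :]
    wts = np.exp(-2.0 * h)
    Xw = Xl * wts[:, None]
    prec = np.eye(q) / prior_var + Xw.T @ Xl
    prec = 0.5 * (prec + prec.T)
    mean = np.linalg.solve(prec, Xw.T @ y)
    L = np.linalg.cholesky(prec)
    for _ in range(max_tries):
        rho = mean + np.linalg.solve(L.T, rng.standard_normal(q))
        if not stability or _ar_stable(rho):
            return rho
    raise RuntimeError(
        f"no stable AR({q}) draw in {max_tries} tries; posterior mass "
        "appears to sit in the non-stationary region"
    )


def sample_idio_sv(
    residuals: np.ndarray,
    h_prior: RandomWalkBlockLaw,
    rng: np.random.Generator,
    h_current: np.ndarray | None = None,
) -> np.ndarray:
    """Update the (T, n) idiosyncratic log-volatility paths series by series."""
    E = np.atleast_2d(np.asarray(residuals, float))
    if E.ndim == 2 and E.shape[0] == 1:
        E = E.T if E.size > 1 else E
    T, n = E.shape
    out = np.empty((T, n))
    for i in range(n):
        cur = None if h_current is None else h_current[:, i]
        out[:, i] = sample_sv_ksc(E[:, i], h_prior, rng, h_current=cur)
    return out
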