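"""Linear-Gaussian state-space core: filtering, path sampling, stochastic
volatility and covariance draws.

This module is the numerical kernel shared by every Gibbs block of the
time-varying-parameter model.  The latent laws of motion are random walks,

    s_t = s_{t-1} + w_t,  w_t ~ N(0, Q),

with the convention that a block's time-variation indicator J = 0 is
expressed as Q = 0, in which case sampled paths are constant over time
(exactly, not merely up to numerical noise).

Stochastic volatility is handled with the standard seven-component normal
mixture approximation to the log chi-squared(1) distribution (Kim, Shephard
and Chib 1998), which linearizes log(resid^2) in the log-volatility so the
same Carter-Kohn machinery applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _kernels

__all__ = [
    "LinearGaussianSS",
    "RandomWalkBlockLaw",
    "KSC_PROBS",
    "KSC_MEANS",
    "KSC_VARS",
    "kalman_filter",
    "kalman_smoother",
    "carter_kohn_sample",
    "sample_sv_ksc",
    "draw_inverse_wishart",
    "sample_q_blocks",
]

# Seven-component mixture approximating the distribution of log(chi2_1).
# Component means are stored as published, i.e. for log(chi2_1) + 1.2704;
# subtract 1.2704 when forming the observation equation.
KSC_PROBS = np.array(
    [0.00730, 0.10556, 0.00002, 0.04395, 0.34001, 0.24566, 0.25750]
)
KSC_MEANS = np.array(
    [-10.12999, -3.97281, -8.56686, 2.77786, 0.61942, 1.79518, -1.08819]
)
KSC_VARS = np.array(
    [5.79596, 2.61369, 5.17950, 0.16735, 0.64009, 0.34023, 1.26261]
)
KSC_OFFSET = 1.2704
#: offset added inside the log to guard log(0) on tiny squared residuals
LOG_SQUARE_OFFSET = 1e-4


@dataclass
class RandomWalkBlockLaw:
    """Random-walk law of motion of one latent block.

    ``time_varying=False`` (indicator J = 0) pins the path to a constant; the
    innovation covariance ``q`` is then ignored.
    """

    time_varying: bool = True
    q: np.ndarray | float = 0.0
    init_mean: np.ndarray | float = 0.0
    init_cov: np.ndarray | float = 4.0


@dataclass
class LinearGaussianSS:
    """A linear-Gaussian state-space model with random-walk states.

    obs_matrices : (T, ny, ns) per-time observation maps Z_t
    obs_cov      : (T, ny, ny) or (ny, ny) observation covariance H_t
    state_cov    : (ns, ns) random-walk innovation covariance Q (0 allowed)
    init_mean    : (ns,) prior state mean
    init_cov     : (ns, ns) prior state covariance
    """

    obs_matrices: np.ndarray
    obs_cov: np.ndarray
    state_cov: np.ndarray
    init_mean: np.ndarray
    init_cov: np.ndarray

    def __post_init__(self):
        self.obs_matrices = np.atleast_3d(np.asarray(self.obs_matrices, float))
        T, ny, ns = self.obs_matrices.shape
        H = np.asarray(self.obs_cov, float)
        if H.ndim == 2:
            H = np.broadcast_to(H, (T, ny, ny)).copy()
        self.obs_cov = H
        self.state_cov = np.atleast_2d(np.asarray(self.state_cov, float))
        self.init_mean = np.atleast_1d(np.asarray(self.init_mean, float))
        self.init_cov = np.atleast_2d(np.asarray(self.init_cov, float))
        if self.state_cov.shape != (ns, ns):
            raise ValueError("state_cov dimension mismatch")
        if self.init_cov.shape != (ns, ns) or self.init_mean.shape != (ns,):
            raise ValueError("initial state moment dimension mismatch")
        if H.shape != (T, ny, ny):
            raise ValueError("obs_cov dimension mismatch")
        for M, name in ((self.state_cov, "state_cov"), (self.init_cov, "init_cov")):
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")

    @property
    def nobs_dim(self) -> int:
        return self.obs_matrices.shape[1]

    @property
    def state_dim(self) -> int:
        return self.obs_matrices.shape[2]

    def _dense_system(self, T: int):
        ns = self.state_dim
        F = np.broadcast_to(np.eye(ns), (T, ns, ns)).copy()
        Q = np.broadcast_to(self.state_cov, (T, ns, ns)).copy()
        return F, Q


def _as_obs(y: np.ndarray, model: LinearGaussianSS) -> np.ndarray:
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape != (model.obs_matrices.shape[0], model.nobs_dim):
        raise ValueError(
            f"observations shaped {y.shape}, expected "
            f"{(model.obs_matrices.shape[0], model.nobs_dim)}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("observations contain non-finite values")
    return y


def kalman_filter(model: LinearGaussianSS, y: np.ndarray):
    """Exact Gaussian filtering recursions.

    Returns ``(filtered_means, filtered_covs, loglik)`` where the
    log-likelihood is the sum of one-step predictive log densities.
    """
    y = _as_obs(y, model)
    T = y.shape[0]
    F, Q = model._dense_system(T)
    att, Ptt, _, _, ll = _kernels.forward_filter(
        np.ascontiguousarray(y),
        np.ascontiguousarray(model.obs_matrices),
        np.ascontiguousarray(model.obs_cov),
        F,
        Q,
        model.init_mean.copy(),
        model.init_cov.copy(),
    )
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood in Kalman filter")
    return att, Ptt, ll


def kalman_smoother(model: LinearGaussianSS, y: np.ndarray):
    """Smoothed state means and covariances (Rauch-Tung-Striebel pass)."""
    y = _as_obs(y, model)
    T = y.shape[0]
    F, Q = model._dense_system(T)
    att, Ptt, atp, Ptp, _ = _kernels.forward_filter(
        np.ascontiguousarray(y),
        np.ascontiguousarray(model.obs_matrices),
        np.ascontiguousarray(model.obs_cov),
        F,
        Q,
        model.init_mean.copy(),
        model.init_cov.copy(),
    )
    return _kernels.rts_smoother(att, Ptt, atp, Ptp, F)


def carter_kohn_sample(
    model: LinearGaussianSS, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw an entire state path from p(states | y).

    Forward Kalman filter followed by backward sampling from the exact
    Gaussian conditionals.  When the innovation covariance is exactly zero
    (indicator J = 0) the conditional path is constant over time: a single
    state is drawn from the final filtered distribution and tiled, so the
    degenerate fixed-coefficient case holds to machine exactness.
    """
    y = _as_obs(y, model)
    T = y.shape[0]
    F, Q = model._dense_system(T)
    att, Ptt, _, _, _ = _kernels.forward_filter(
        np.ascontiguousarray(y),
        np.ascontiguousarray(model.obs_matrices),
        np.ascontiguousarray(model.obs_cov),
        F,
        Q,
        model.init_mean.copy(),
        model.init_cov.copy(),
    )
    ns = model.state_dim
    if not np.any(model.state_cov):
        P = 0.5 * (Ptt[-1] + Ptt[-1].T) + 1e-12 * np.eye(ns)
        L = np.linalg.cholesky(P)
        s = att[-1] + L @ rng.standard_normal(ns)
        return np.tile(s, (T, 1))
    normals = rng.standard_normal((T, ns))
    return _kernels.ck_backward(att, Ptt, F, Q, normals)


def sample_sv_ksc(
    residuals: np.ndarray,
    h_prior: RandomWalkBlockLaw,
    rng: np.random.Generator,
    h_current: np.ndarray | None = None,
) -> np.ndarray:
    """One Gibbs update of a log-volatility path h_t = log sigma_t.

    The observation residuals e_t ~ N(0, exp(2 h_t)) are transformed to
    log(e_t^2 + c); mixture indicators are drawn conditional on the current
    h path; the resulting conditionally Gaussian model is passed to the
    Carter-Kohn sampler.  Returns a (T,) draw of h.
    """
    e = np.asarray(residuals, float).ravel()
    if e.size == 0 or not np.all(np.isfinite(e)):
        raise ValueError("residuals must be a non-empty finite array")
    if np.all(e == 0.0):
        raise ValueError("degenerate input: residuals are identically zero")
    T = e.size
    ystar = np.log(e**2 + LOG_SQUARE_OFFSET)
    if h_current is None:
        h_current = np.full(T, 0.5 * np.log(np.var(e) + LOG_SQUARE_OFFSET))
    s = _draw_mixture_indicators(ystar, 2.0 * np.asarray(h_current, float), rng)
    obs = ystar - (KSC_MEANS[s] - KSC_OFFSET)
    Z = np.full((T, 1, 1), 2.0)
    H = (KSC_VARS[s])[:, None, None]
    q = float(np.atleast_1d(h_prior.q).ravel()[0]) if h_prior.time_varying else 0.0
    model = LinearGaussianSS(
        obs_matrices=Z,
        obs_cov=H,
        state_cov=np.array([[q]]),
        init_mean=np.atleast_1d(h_prior.init_mean).astype(float),
        init_cov=np.atleast_2d(h_prior.init_cov).astype(float),
    )
    return carter_kohn_sample(model, obs, rng)[:, 0]


def _draw_mixture_indicators(
    ystar: np.ndarray, mean_shift: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample KSC mixture component indicators, vectorized over cells.

    ``ystar`` and ``mean_shift`` may have any common shape; the categorical
    posterior over the 7 components is formed cell-wise.
    """
    resid = ystar[..., None] - mean_shift[..., None] - (KSC_MEANS - KSC_OFFSET)
    logp = (
        np.log(KSC_PROBS)
        - 0.5 * np.log(KSC_VARS)
        - 0.5 * resid**2 / KSC_VARS
    )
    logp -= logp.max(axis=-1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=-1, keepdims=True)
    cdf = np.cumsum(p, axis=-1)
    u = rng.random(ystar.shape + (1,))
    return (u > cdf).sum(axis=-1)


def draw_inverse_wishart(
    scale: np.ndarray, dof: float, rng: np.random.Generator
) -> np.ndarray:
    """A draw from the inverse-Wishart IW(scale, dof); always symmetric PD."""
    scale = np.atleast_2d(np.asarray(scale, float))
    d = scale.shape[0]
    if scale.shape != (d, d) or not np.allclose(scale, scale.T, atol=1e-8):
        raise ValueError("scale must be a symmetric square matrix")
    if dof <= d - 1:
        raise ValueError(f"dof must exceed dim - 1 = {d - 1}, got {dof}")
    try:
        np.linalg.cholesky(scale)
    except np.linalg.LinAlgError as exc:
        raise ValueError("scale matrix is not positive definite") from exc
    draw = stats.invwishart.rvs(df=dof, scale=scale, random_state=rng)
    draw = np.atleast_2d(draw)
    return 0.5 * (draw + draw.T)


def sample_q_blocks(
    increments: np.ndarray,
    prior_scale: np.ndarray,
    prior_dof: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate inverse-Wishart update of a random-walk innovation covariance.

    ``increments`` is a (T-1, d) array of successive state differences; the
    posterior is IW(prior_scale + sum_t d_t d_t', prior_dof + (T-1)).
    """
    inc = np.atleast_2d(np.asarray(increments, float))
    scale = np.atleast_2d(np.asarray(prior_scale, float))
    post_scale = scale + inc.T @ inc
    post_dof = prior_dof + inc.shape[0]
    return draw_inverse_wishart(post_scale, post_dof, rng)
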