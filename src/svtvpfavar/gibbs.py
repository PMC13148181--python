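"""Gibbs sampler for the TVP-FAVAR with stochastic volatility.

The sweep cycles through the conditional blocks

    [factors (joint mode only)] -> loadings / idiosyncratic AR / idiosyncratic SV
    -> VAR coefficients B_t -> triangular elements alpha_t -> log sigma_t
    -> random-walk innovation covariances Q_B, Q_alpha, Q_sigma,

each drawn from its exact conditional (Carter-Kohn for the three latent
random-walk paths, the KSC mixture device for the volatilities, conjugate
inverse-Wishart updates for the Q's).  Priors follow the usual
Minnesota-prior Bayesian VAR practice: the initial coefficient state is
N(Bhat, Vhat) with own-first-lag mean 0.9, alpha_0 ~ N(0, 4I),
log sigma_0 ~ N(0, 4I), and

    Q_B     ~ IW(0.005 (dim B + 1) Vhat, dim B + 1)
    Q_alpha ~ IW(0.01  (dim a + 1) I,    dim a + 1)   per equation block
    Q_sigma ~ IW(0.0001 (dim s + 1) I,   dim s + 1).

Setting a block's time-variation indicator to False pins its innovation
covariance to zero, so sampled paths are constant and the model collapses
to the fixed-coefficient VAR.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .factors import IdiosyncraticModel, sample_idio_ar, sample_loadings
from .irf import build_companion
from .statespace import (
    KSC_MEANS,
    KSC_OFFSET,
    KSC_VARS,
    LOG_SQUARE_OFFSET,
    _draw_mixture_indicators,
    sample_q_blocks,
)

__all__ = [
    "ModelDims",
    "PriorConfig",
    "SamplerConfig",
    "PosteriorDraws",
    "run_gibbs",
    "GibbsBlockError",
]

logger = logging.getLogger(__name__)


class GibbsBlockError(RuntimeError):
    """Numerical failure inside one Gibbs block, tagged with block and sweep."""


@dataclass
class ModelDims:
    """Dimensions of the augmented system."""

    k: int  # latent factors
    l: int  # core observables
    p: int  # VAR lag order
    q: int = 1  # idiosyncratic AR order
    n: int = 0  # panel width (0 when fitting the VAR alone)
    T: int = 0  # quarters in the raw sample

    @property
    def m(self) -> int:
        """Augmented dimension k + l + 1."""
        return self.k + self.l + 1

    @property
    def mb(self) -> int:
        """Length of the stacked coefficient vector B_t."""
        return self.m * self.m * self.p

    @property
    def na(self) -> int:
        """Free elements of the lower-triangular A_t."""
        return self.m * (self.m - 1) // 2

    def validate(self) -> None:
        if self.k < 0 or self.l < 0 or self.p < 1 or self.q < 0:
            raise ValueError("invalid dimensions")
        if self.m != self.k + self.l + 1:
            raise AssertionError
        if self.T and self.T <= self.p:
            raise ValueError("T must exceed p")


@dataclass
class PriorConfig:
    """Prior hyperparameters of the Gibbs sampler."""

    b0_mean: np.ndarray
    b0_cov: np.ndarray
    alpha0_var: float = 4.0
    logsigma0_var: float = 4.0
    q_b_factor: float = 0.005
    q_a_factor: float = 0.01
    q_s_factor: float = 0.0001
    loading_prior_var: float = 10.0
    idio_h_q: float = 0.01

    @classmethod
    def minnesota(
        cls,
        y: np.ndarray,
        dims: ModelDims,
        own_lag_mean: float = 0.9,
        overall_tightness: float = 0.05,
        cross_tightness: float = 0.5,
        lag_decay: float = 2.0,
        **kwargs,
    ) -> "PriorConfig":
        """Minnesota-form prior moments for the initial coefficient state.

        The prior mean puts ``own_lag_mean`` on each variable's own first
        lag and zero elsewhere; prior variances shrink cross-equation terms
        by ``cross_tightness`` (scale-adjusted by per-equation AR(p)
        residual variances) and decay with the lag as 1/lag**lag_decay.
        """
        m, p, mb = dims.m, dims.p, dims.mb
        y = np.asarray(y, float)
        svar = np.empty(m)
        for i in range(m):
            svar[i] = _ar_resid_var(y[:, i], p)
        mean = np.zeros(mb)
        var = np.empty(mb)
        for lag in range(p):
            for j in range(m):  # regressor variable
                for i in range(m):  # equation
                    pos = lag * m * m + j * m + i
                    if i == j:
                        if lag == 0:
                            mean[pos] = own_lag_mean
                        var[pos] = overall_tightness / (lag + 1) ** lag_decay
                    else:
                        var[pos] = (
                            overall_tightness
                            * cross_tightness
                            * svar[i]
                            / (svar[j] * (lag + 1) ** lag_decay)
                        )
        return cls(b0_mean=mean, b0_cov=np.diag(var), **kwargs)

    @classmethod
    def diffuse(cls, dims: ModelDims, scale: float = 10.0, **kwargs) -> "PriorConfig":
        """Flat-ish Gaussian prior on the initial coefficient state."""
        return cls(
            b0_mean=np.zeros(dims.mb),
            b0_cov=scale * np.eye(dims.mb),
            **kwargs,
        )

    def q_b_prior(self) -> tuple[np.ndarray, float]:
        mb = self.b0_mean.size
        return self.q_b_factor * (mb + 1) * self.b0_cov, mb + 1

    def q_a_prior(self, block_dim: int) -> tuple[np.ndarray, float]:
        d = block_dim
        return self.q_a_factor * (d + 1) * np.eye(d), d + 1

    def q_s_prior(self, m: int) -> tuple[np.ndarray, float]:
        return self.q_s_factor * (m + 1) * np.eye(m), m + 1


def _ar_resid_var(x: np.ndarray, p: int) -> float:
    """Residual variance of a univariate AR(p) fit (used to scale the prior)."""
    T = x.size
    if T <= p + 2:
        return float(np.var(x))
    Y = x[p:]
    X = np.column_stack([x[p - j : T - j] for j in range(1, p + 1)])
    X = np.column_stack([np.ones(T - p), X])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(len(Y) - X.shape[1], 1)
    return float(max(resid @ resid / dof, 1e-12))


@dataclass
class SamplerConfig:
    """Run-length and mode switches of the Gibbs sampler."""

    n_draws: int = 10_000
    n_burn: int = 2_000
    thin: int = 5
    seed: int = 0
    mode: str = "two_step"  # or "joint"
    time_varying_b: bool = True
    time_varying_a: bool = True
    time_varying_s: bool = True

    def __post_init__(self):
        if self.n_draws <= 0 or self.thin < 1 or self.n_burn < 0:
            raise ValueError("need n_draws > 0, thin >= 1, n_burn >= 0")
        if self.n_burn >= self.n_draws:
            raise ValueError("n_burn must be smaller than n_draws")
        if self.mode not in ("two_step", "joint"):
            raise ValueError("mode must be 'two_step' or 'joint'")

    @property
    def n_retained(self) -> int:
        return (self.n_draws - self.n_burn) // self.thin


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws of all latent paths and covariances.

    Path arrays are indexed (draw, time, component) on the effective sample
    (the first p quarters are consumed as initial lags).
    """

    dims: ModelDims
    b_path: np.ndarray  # (ndraw, T, m^2 p)
    alpha_path: np.ndarray  # (ndraw, T, m(m-1)/2)
    sigma_path: np.ndarray  # (ndraw, T, m)
    q_b: np.ndarray  # (ndraw, mb, mb)
    q_a: np.ndarray  # (ndraw, na, na) block-diagonal by equation
    q_s: np.ndarray  # (ndraw, m, m)
    factor_path: np.ndarray | None = None  # (ndraw, T0, k) in joint mode
    loadings: np.ndarray | None = None  # (ndraw, n, m) when a panel is modelled
    var_names: list[str] | None = None
    times: list[str] | None = None

    @property
    def n_retained(self) -> int:
        return self.b_path.shape[0]

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for name in ("b_path", "alpha_path", "sigma_path", "q_b", "q_a", "q_s"):
                fh.create_dataset(name, data=getattr(self, name))
            if self.factor_path is not None:
                fh.create_dataset("factor_path", data=self.factor_path)
            if self.loadings is not None:
                fh.create_dataset("loadings", data=self.loadings)
            fh.attrs["k"] = self.dims.k
            fh.attrs["l"] = self.dims.l
            fh.attrs["p"] = self.dims.p
            fh.attrs["q"] = self.dims.q
            if self.times is not None:
                fh.create_dataset(
                    "times", data=np.array(self.times, dtype="S16")
                )

    @classmethod
    def load_hdf5(cls, path) -> "PosteriorDraws":
        import h5py

        with h5py.File(path, "r") as fh:
            k, l, p, q = (int(fh.attrs[a]) for a in ("k", "l", "p", "q"))
            arrays = {
                name: fh[name][()]
                for name in ("b_path", "alpha_path", "sigma_path", "q_b", "q_a", "q_s")
            }
            factor = fh["factor_path"][()] if "factor_path" in fh else None
            load = fh["loadings"][()] if "loadings" in fh else None
            times = (
                [t.decode() for t in fh["times"][()]] if "times" in fh else None
            )
        T = arrays["b_path"].shape[1]
        dims = ModelDims(k=k, l=l, p=p, q=q, T=T + p)
        return cls(
            dims=dims,
            factor_path=factor,
            loadings=load,
            times=times,
            **arrays,
        )


def _ck_draw(y, Z, H, Q, a0, P0, rng):
    """Carter-Kohn draw with random-walk transition; Q == 0 yields a constant path."""
    T = y.shape[0]
    ns = a0.size
    F = np.broadcast_to(np.eye(ns), (T, ns, ns)).copy()
    Qs = np.broadcast_to(np.atleast_2d(Q), (T, ns, ns)).copy()
    att, Ptt, _, _, _ = _kernels.forward_filter(
        np.ascontiguousarray(y), np.ascontiguousarray(Z),
        np.ascontiguousarray(H), F, Qs, a0.astype(float), P0.astype(float)
    )
    if not np.any(Q):
        P = 0.5 * (Ptt[-1] + Ptt[-1].T) + 1e-12 * np.eye(ns)
        L = np.linalg.cholesky(P)
        s = att[-1] + L @ rng.standard_normal(ns)
        return np.tile(s, (T, 1))
    normals = rng.standard_normal((T, ns))
    return _kernels.ck_backward(att, Ptt, F, Qs, normals)


def _build_var_regressors(y: np.ndarray, p: int):
    """Lagged-design arrays: W (T_eff, m p) and Z (T_eff, m, m^2 p)."""
    T0, m = y.shape
    T = T0 - p
    W = np.hstack([y[p - j - 1 : T0 - j - 1] for j in range(p)])
    Z = np.zeros((T, m, m * m * p))
    eye = np.eye(m)
    for t in range(T):
        Z[t] = np.kron(W[t], eye)
    return W, Z


def _tri_indices(m: int):
    rows, cols = [], []
    for i in range(1, m):
        for j in range(i):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


def _a_matrices(alpha_path: np.ndarray, m: int) -> np.ndarray:
    """(T, m, m) unit-diagonal lower-triangular A_t, vectorized over time."""
    T = alpha_path.shape[0]
    rows, cols = _tri_indices(m)
    A = np.broadcast_to(np.eye(m), (T, m, m)).copy()
    A[:, rows, cols] = alpha_path
    return A


def _omega_and_impact(alpha_path, h_path, m):
    """Per-time impact A^-1 S and reduced-form covariance Omega (batched)."""
    sig = np.exp(h_path)
    A = _a_matrices(alpha_path, m)
    S = np.zeros(A.shape)
    ar = np.arange(m)
    S[:, ar, ar] = sig
    impact = np.linalg.solve(A, S)
    omega = impact @ np.swapaxes(impact, 1, 2)
    return impact, omega


def run_gibbs(
    y: np.ndarray,
    dims: ModelDims,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    panel: np.ndarray | None = None,
    var_names: list[str] | None = None,
    times: list[str] | None = None,
    fixed_idio: IdiosyncraticModel | None = None,
) -> PosteriorDraws:
    """Run the full block Gibbs sweep and return retained draws.

    Parameters
    ----------
    y : (T0, m) array
        The augmented series [factors, core observables, uncertainty index]
        (in two-step mode the factor block holds the PCA estimates).
    dims : ModelDims
    priors : PriorConfig, optional
        Defaults to the Minnesota prior built from ``y``.
    sampler : SamplerConfig, optional
    panel : (T0, n) array, optional
        Standardized indicator panel; when given, loadings and
        idiosyncratic AR/SV blocks are sampled too, and in joint mode the
        factor path itself is re-drawn each sweep.
    """
    y = np.asarray(y, float)
    dims.validate()
    sampler = sampler or SamplerConfig()
    priors = priors or PriorConfig.minnesota(y, dims)
    rng = np.random.default_rng(sampler.seed)
    T0, m = y.shape
    if m != dims.m:
        raise ValueError(f"y has {m} columns but dims.m = {dims.m}")
    p, mb, na = dims.p, dims.mb, dims.na
    T = T0 - p
    joint = sampler.mode == "joint" and panel is not None
    if joint and dims.q > max(dims.p - 1, 0):
        raise NotImplementedError(
            "joint factor sampling requires idiosyncratic AR order q <= p - 1"
        )
    if panel is not None:
        panel = np.asarray(panel, float)
        n = panel.shape[1]
    else:
        n = 0

    W, Zb = _build_var_regressors(y, p)
    yv = y[p:]

    # --- initial values ---------------------------------------------------
    # no intercept: inputs are stationary and standardized
    bols, *_ = np.linalg.lstsq(W, yv, rcond=None)
    b0 = np.concatenate(
        [bols[j * m : (j + 1) * m].T.ravel(order="F") for j in range(p)]
    )
    b_path = np.tile(b0, (T, 1))
    alpha_path = np.zeros((T, na))
    resid0 = yv - W @ bols
    h_path = np.tile(
        0.5 * np.log(np.maximum(resid0.var(axis=0), 1e-8)), (T, 1)
    )
    qb_scale, qb_dof = priors.q_b_prior()
    q_b = qb_scale / (qb_dof + mb + 1)
    q_a_blocks = []
    for j in range(1, m):
        qa_scale, qa_dof = priors.q_a_prior(j)
        q_a_blocks.append(qa_scale / (qa_dof + j + 1))
    qs_scale, qs_dof = priors.q_s_prior(m)
    q_s = qs_scale / (qs_dof + m + 1)

    lam = None
    idio = fixed_idio
    factor_now = y[:, : dims.k].copy()
    # rotation/scale/sign reference pinning the factor identification;
    # purged of the observed block, like every subsequent draw
    factor_ref = _identify_factors(
        factor_now,
        factor_now / factor_now.std(axis=0, ddof=1),
        observed=y[:, dims.k :],
    )
    if joint:
        factor_now = factor_ref.copy()
        y = y.copy()
        y[:, : dims.k] = factor_now
        W, Zb = _build_var_regressors(y, p)
        yv = y[p:]
    if panel is not None and idio is None:
        rho0 = np.zeros((n, dims.q))
        hpan0 = np.tile(
            0.5 * np.log(np.maximum(panel.var(axis=0), 1e-8)), (T0, 1)
        )
        idio = IdiosyncraticModel(rho=rho0, h_path=hpan0, q_h=priors.idio_h_q)

    keep = sampler.n_retained
    out_b = np.empty((keep, T, mb))
    out_a = np.empty((keep, T, na))
    out_s = np.empty((keep, T, m))
    out_qb = np.empty((keep, mb, mb))
    out_qa = np.empty((keep, na, na))
    out_qs = np.empty((keep, m, m))
    out_f = np.empty((keep, T0, dims.k)) if joint else None
    out_lam = np.empty((keep, n, m)) if panel is not None else None

    block_time: dict[str, float] = {}
    kept = 0
    for sweep in range(sampler.n_draws):
        try:
            # ---- factors (joint mode) ---------------------------------
            if joint:
                t0 = time.perf_counter()
                factor_now = _sample_factors_dk(
                    y, panel, lam, idio, b_path, alpha_path, h_path, dims, rng
                )
                factor_now = _identify_factors(
                    factor_now, factor_ref, observed=y[:, dims.k :]
                )
                y = y.copy()
                y[:, : dims.k] = factor_now
                W, Zb = _build_var_regressors(y, p)
                yv = y[p:]
                block_time["factors"] = block_time.get("factors", 0.0) + (
                    time.perf_counter() - t0
                )
            # ---- loadings and idiosyncratic blocks --------------------
            if panel is not None:
                t0 = time.perf_counter()
                lam_obj = sample_loadings(
                    panel,
                    y[:, : dims.k],
                    y[:, dims.k : dims.k + dims.l],
                    y[:, -1],
                    idio,
                    priors.loading_prior_var,
                    rng,
                )
                lam = lam_obj.full
                if fixed_idio is None:
                    u = panel - np.hstack(
                        [y[:, : dims.k], y[:, dims.k : dims.k + dims.l], y[:, -1:]]
                    ) @ lam.T
                    for i in range(n):
                        if dims.q > 0:
                            idio.rho[i] = sample_idio_ar(
                                u[:, i], dims.q, idio.h_path[:, i], rng
                            )
                        eps_i = _quasi_diff_1d(u[:, i], idio.rho[i])
                        h_i = _sv_update(
                            eps_i,
                            idio.h_path[dims.q :, i],
                            idio.q_h,
                            priors.logsigma0_var,
                            rng,
                        )
                        idio.h_path[dims.q :, i] = h_i
                        if dims.q > 0:
                            idio.h_path[: dims.q, i] = h_i[0]
                block_time["panel"] = block_time.get("panel", 0.0) + (
                    time.perf_counter() - t0
                )
            # ---- B block ----------------------------------------------
            t0 = time.perf_counter()
            _, omega = _omega_and_impact(alpha_path, h_path, m)
            qb_now = q_b if sampler.time_varying_b else np.zeros_like(q_b)
            b_path = _ck_draw(
                yv, Zb, omega, qb_now, priors.b0_mean, priors.b0_cov, rng
            )
            block_time["b"] = block_time.get("b", 0.0) + (time.perf_counter() - t0)
            # ---- alpha blocks -----------------------------------------
            t0 = time.perf_counter()
            nu = yv - np.einsum("tij,tj->ti", Zb, b_path)
            pos = 0
            sig2 = np.exp(2.0 * h_path)
            for j in range(1, m):
                Zj = -nu[:, :j].reshape(T, 1, j)
                Hj = sig2[:, j].reshape(T, 1, 1)
                Qj = (
                    q_a_blocks[j - 1]
                    if sampler.time_varying_a
                    else np.zeros((j, j))
                )
                path_j = _ck_draw(
                    nu[:, j].reshape(T, 1),
                    Zj,
                    Hj,
                    Qj,
                    np.zeros(j),
                    priors.alpha0_var * np.eye(j),
                    rng,
                )
                alpha_path[:, pos : pos + j] = path_j
                pos += j
            block_time["alpha"] = block_time.get("alpha", 0.0) + (
                time.perf_counter() - t0
            )
            # ---- volatility block -------------------------------------
            t0 = time.perf_counter()
            estar = np.einsum("tij,tj->ti", _a_matrices(alpha_path, m), nu)
            ystar = np.log(estar**2 + LOG_SQUARE_OFFSET)
            s_ix = _draw_mixture_indicators(ystar, 2.0 * h_path, rng)
            obs = ystar - (KSC_MEANS[s_ix] - KSC_OFFSET)
            Zs = np.broadcast_to(2.0 * np.eye(m), (T, m, m)).copy()
            Hs = np.zeros((T, m, m))
            Hs[:, np.arange(m), np.arange(m)] = KSC_VARS[s_ix]
            qs_now = q_s if sampler.time_varying_s else np.zeros_like(q_s)
            h_path = _ck_draw(
                obs,
                Zs,
                Hs,
                qs_now,
                np.zeros(m),
                priors.logsigma0_var * np.eye(m),
                rng,
            )
            block_time["sv"] = block_time.get("sv", 0.0) + (
                time.perf_counter() - t0
            )
            # ---- Q blocks ---------------------------------------------
            t0 = time.perf_counter()
            if sampler.time_varying_b:
                q_b = sample_q_blocks(np.diff(b_path, axis=0), qb_scale, qb_dof, rng)
            pos = 0
            for j in range(1, m):
                if sampler.time_varying_a:
                    qa_scale, qa_dof = priors.q_a_prior(j)
                    q_a_blocks[j - 1] = sample_q_blocks(
                        np.diff(alpha_path[:, pos : pos + j], axis=0),
                        qa_scale,
                        qa_dof,
                        rng,
                    )
                pos += j
            if sampler.time_varying_s:
                q_s = sample_q_blocks(np.diff(h_path, axis=0), qs_scale, qs_dof, rng)
            block_time["q"] = block_time.get("q", 0.0) + (time.perf_counter() - t0)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            raise GibbsBlockError(
                f"numerical failure at sweep {sweep}: {exc}"
            ) from exc

        if sweep >= sampler.n_burn and (sweep - sampler.n_burn) % sampler.thin == 0:
            if kept < keep:
                out_b[kept] = b_path
                out_a[kept] = alpha_path
                out_s[kept] = np.exp(h_path)
                out_qb[kept] = q_b
                qa_full = np.zeros((na, na))
                pos = 0
                for j in range(1, m):
                    qa_full[pos : pos + j, pos : pos + j] = q_a_blocks[j - 1]
                    pos += j
                out_qa[kept] = qa_full
                out_qs[kept] = q_s
                if joint:
                    out_f[kept] = factor_now
                if panel is not None:
                    out_lam[kept] = lam
                kept += 1
        if sweep and sweep % 500 == 0:
            logger.info("gibbs sweep %d/%d", sweep, sampler.n_draws)

    logger.info(
        "gibbs done: %d retained draws; block seconds %s",
        kept,
        {k: round(v, 2) for k, v in block_time.items()},
    )
    return PosteriorDraws(
        dims=dims,
        b_path=out_b[:kept],
        alpha_path=out_a[:kept],
        sigma_path=out_s[:kept],
        q_b=out_qb[:kept],
        q_a=out_qa[:kept],
        q_s=out_qs[:kept],
        factor_path=out_f[:kept] if joint else None,
        loadings=out_lam[:kept] if panel is not None else None,
        var_names=var_names,
        times=times,
    )


def _identify_factors(
    f: np.ndarray, ref: np.ndarray, observed: np.ndarray | None = None
) -> np.ndarray:
    """Resolve the indeterminacies of a latent factor draw.

    The observation equation is invariant under (i) adding any combination
    of the *observed* variables to the factors (loadings compensate), and
    (ii) any invertible k x k transformation of the factor space.  Each
    draw is therefore canonicalized: projected orthogonal to the observed
    block, whitened to identity sample covariance (which removes scale and
    shear), rotated (orthogonal Procrustes) onto a fixed reference basis
    (the PCA initialization) and sign-matched to the reference.  This is a
    reparameterization along the likelihood's flat directions, so fit is
    untouched while draw averages become meaningful.
    """
    from scipy.linalg import orthogonal_procrustes

    fs = f - f.mean(axis=0)
    if observed is not None and observed.size:
        obs = observed - observed.mean(axis=0)
        coef, *_ = np.linalg.lstsq(obs, fs, rcond=None)
        fs = fs - obs @ coef
    cov = fs.T @ fs / (fs.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    white = vecs @ np.diag(1.0 / np.sqrt(np.maximum(vals, 1e-12))) @ vecs.T
    fs = fs @ white
    R, _ = orthogonal_procrustes(fs, ref - ref.mean(axis=0))
    out = fs @ R
    for j in range(out.shape[1]):
        if np.dot(out[:, j], ref[:, j] - ref[:, j].mean()) < 0:
            out[:, j] *= -1.0
    return out


def _quasi_diff_1d(x: np.ndarray, rho: np.ndarray) -> np.ndarray:
    q = len(rho)
    if q == 0:
        return x
    out = x[q:].copy()
    for j in range(1, q + 1):
        out -= rho[j - 1] * x[q - j : len(x) - j]
    return out


def _sv_update(eps, h_current, q_h, init_var, rng):
    """Scalar KSC volatility update used for the idiosyncratic series."""
    ystar = np.log(eps**2 + LOG_SQUARE_OFFSET)
    s = _draw_mixture_indicators(ystar, 2.0 * h_current, rng)
    obs = (ystar - (KSC_MEANS[s] - KSC_OFFSET)).reshape(-1, 1)
    T = len(obs)
    Z = np.full((T, 1, 1), 2.0)
    H = KSC_VARS[s].reshape(T, 1, 1)
    return _ck_draw(
        obs,
        Z,
        H,
        np.array([[q_h]]),
        np.zeros(1),
        init_var * np.eye(1),
        rng,
    )[:, 0]


def _sample_factors_dk(
    y, panel, lam, idio, b_path, alpha_path, h_path, dims, rng
):
    """Joint-mode factor draw via the Durbin-Koopman simulation smoother.

    The companion state xi_t = [y_t', ..., y_{t-p+1}']' evolves with the
    current coefficient draw; observations are the quasi-differenced panel
    (noise exp(2 h_it)) plus the core observables and the uncertainty index
    observed with negligible noise.  A draw from p(states | data) is the
    unconditional simulation plus the smoother mean correction.
    """
    k, l, p, q = dims.k, dims.l, dims.p, dims.q
    m = dims.m
    T0, n = panel.shape
    T = T0 - p
    ns = m * p
    if lam is None:
        lam = np.hstack(
            [
                np.linalg.lstsq(
                    np.hstack([y[:, :k], y[:, k:]]), panel, rcond=None
                )[0].T[:, :k],
                np.zeros((n, l + 1)),
            ]
        )
    rho = idio.rho
    hp = idio.h_path
    ny = n + l + 1
    Z = np.zeros((T, ny, ns))
    H = np.zeros((T, ny, ny))
    obs = np.zeros((T, ny))
    F = np.zeros((T, ns, ns))
    Q = np.zeros((T, ns, ns))
    _, omega = _omega_and_impact(alpha_path, h_path, m)
    sel = np.zeros((l + 1, m))
    sel[:, k:] = np.eye(l + 1)
    for t in range(T):
        ty = t + p
        F[t] = build_companion(b_path[t], m, p)
        Q[t][:m, :m] = omega[t]
        # quasi-differenced panel rows
        xt = panel[ty].copy()
        Z[t, :n, :m] = lam
        for i in range(1, q + 1):
            xt -= rho[:, i - 1] * panel[ty - i]
            Z[t, :n, i * m : (i + 1) * m] -= rho[:, i - 1][:, None] * lam
        obs[t, :n] = xt
        H[t, :n, :n] = np.diag(np.exp(2.0 * hp[ty]))
        # exactly observed core block and uncertainty index
        Z[t, n:, :m] = sel
        obs[t, n:] = y[ty, k:]
        H[t, n:, n:] = 1e-8 * np.eye(l + 1)
    a0 = np.concatenate([y[p - 1 - i] for i in range(p)])
    P0 = np.eye(ns)

    # unconditional simulation
    xi_plus = np.empty((T, ns))
    y_plus = np.empty((T, ny))
    state = a0 + np.linalg.cholesky(P0) @ rng.standard_normal(ns)
    for t in range(T):
        w = np.zeros(ns)
        Lw = np.linalg.cholesky(omega[t] + 1e-12 * np.eye(m))
        w[:m] = Lw @ rng.standard_normal(m)
        state = F[t] @ state + w
        xi_plus[t] = state
        noise = np.sqrt(np.diag(H[t])) * rng.standard_normal(ny)
        y_plus[t] = Z[t] @ state + noise

    att, Ptt, atp, Ptp, _ = _kernels.forward_filter(obs, Z, H, F, Q, a0, P0)
    sm_y, _ = _kernels.rts_smoother(att, Ptt, atp, Ptp, F)
    att2, Ptt2, atp2, Ptp2, _ = _kernels.forward_filter(
        y_plus, Z, H, F, Q, a0, P0
    )
    sm_plus, _ = _kernels.rts_smoother(att2, Ptt2, atp2, Ptp2, F)
    draw = xi_plus + sm_y - sm_plus

    f_new = y[:, :k].copy()
    f_new[p:] = draw[:, :k]
    return f_new
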