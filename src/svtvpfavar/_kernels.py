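"""Compiled linear-Gaussian state-space kernels.

These are the innermost loops of the Gibbs sampler: the Kalman forward
filter, the Rauch-Tung-Striebel smoother and the Carter-Kohn backward
sampler, all for a model

    y_t = Z_t s_t + e_t,   e_t ~ N(0, H_t)
    s_t = F_t s_{t-1} + w_t,  w_t ~ N(0, Q_t),   s_0 ~ N(a0, P0)

with every system matrix allowed to vary over time.  Randomness enters the
backward sampler only through a pre-drawn array of standard normals so the
kernels themselves are pure functions.

Numerical hygiene: covariances are symmetrized at every step and a 1e-10
ridge is added before any Cholesky factorization or inverse.
"""

import numpy as np
from numba import njit

_LOG2PI = 1.8378770664093453
_RIDGE = 1e-10


@njit(cache=True)
def _sym(a):
    return 0.5 * (a + a.T)


@njit(cache=True)
def forward_filter(y, Z, H, F, Q, a0, P0):
    """Kalman forward pass.

    Parameters are dense arrays: y (T, ny), Z (T, ny, ns), H (T, ny, ny),
    F (T, ns, ns), Q (T, ns, ns), a0 (ns,), P0 (ns, ns).

    Returns filtered means/covs, one-step predicted means/covs and the
    log-likelihood (sum of predictive log densities).
    """
    T, ny = y.shape
    ns = a0.shape[0]
    att = np.empty((T, ns))
    Ptt = np.empty((T, ns, ns))
    atp = np.empty((T, ns))
    Ptp = np.empty((T, ns, ns))
    a = a0.copy()
    P = P0.copy()
    loglik = 0.0
    eye_ny = np.eye(ny)
    for t in range(T):
        ap = F[t] @ a
        Pp = _sym(F[t] @ P @ F[t].T + Q[t])
        atp[t] = ap
        Ptp[t] = Pp
        v = y[t] - Z[t] @ ap
        PZ = Pp @ Z[t].T
        S = _sym(Z[t] @ PZ + H[t]) + _RIDGE * eye_ny
        L = np.linalg.cholesky(S)
        # whitened innovation and gain via triangular solves
        w = np.linalg.solve(L, v)
        logdet = 0.0
        for i in range(ny):
            logdet += np.log(L[i, i])
        loglik += -0.5 * ny * _LOG2PI - logdet - 0.5 * (w @ w)
        Sinv = np.linalg.inv(S)
        K = PZ @ Sinv
        a = ap + K @ v
        P = _sym(Pp - K @ Z[t] @ Pp)
        att[t] = a
        Ptt[t] = P
    return att, Ptt, atp, Ptp, loglik


@njit(cache=True)
def rts_smoother(att, Ptt, atp, Ptp, F):
    """Rauch-Tung-Striebel smoothed means and covariances."""
    T, ns = att.shape
    asm = np.empty((T, ns))
    Psm = np.empty((T, ns, ns))
    asm[T - 1] = att[T - 1]
    Psm[T - 1] = Ptt[T - 1]
    eye_ns = np.eye(ns)
    for t in range(T - 2, -1, -1):
        Pinv = np.linalg.inv(Ptp[t + 1] + _RIDGE * eye_ns)
        G = Ptt[t] @ F[t + 1].T @ Pinv
        asm[t] = att[t] + G @ (asm[t + 1] - atp[t + 1])
        Psm[t] = _sym(Ptt[t] + G @ (Psm[t + 1] - Ptp[t + 1]) @ G.T)
    return asm, Psm


@njit(cache=True)
def ck_backward(att, Ptt, F, Q, normals):
    """Carter-Kohn backward sampling given filtered moments.

    ``normals`` is a (T, ns) array of standard normals; the draw is a
    deterministic function of it, so seeding happens in the caller.
    """
    T, ns = att.shape
    path = np.empty((T, ns))
    eye_ns = np.eye(ns)
    P = _sym(Ptt[T - 1]) + _RIDGE * eye_ns
    L = np.linalg.cholesky(P)
    path[T - 1] = att[T - 1] + L @ normals[T - 1]
    for t in range(T - 2, -1, -1):
        Fp = F[t + 1]
        Pp = _sym(Fp @ Ptt[t] @ Fp.T + Q[t + 1]) + _RIDGE * eye_ns
        G = Ptt[t] @ Fp.T @ np.linalg.inv(Pp)
        m = att[t] + G @ (path[t + 1] - Fp @ att[t])
        V = _sym(Ptt[t] - G @ Fp @ Ptt[t]) + _RIDGE * eye_ns
        L = np.linalg.cholesky(V)
        path[t] = m + L @ normals[t]
    return path
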