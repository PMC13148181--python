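"""MCMC convergence diagnostics and posterior path summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "geweke_z",
    "inefficiency_factor",
    "posterior_summary",
    "PathSummary",
    "ConvergenceReport",
]


def _parzen_weights(K: int) -> np.ndarray:
    u = np.arange(1, K + 1) / K
    w = np.where(u <= 0.5, 1 - 6 * u**2 + 6 * u**3, 2 * (1 - u) ** 3)
    return w


def _spectral_variance(x: np.ndarray) -> float:
    """Long-run variance (spectral density at frequency zero) of a chain.

    Parzen-tapered autocovariance sum with bandwidth 4 (len/100)^0.25.
    """
    x = np.asarray(x, float)
    n = x.size
    xc = x - x.mean()
    K = max(int(4 * (n / 100.0) ** 0.25), 1)
    gamma0 = xc @ xc / n
    s = gamma0
    w = _parzen_weights(K)
    for k in range(1, K + 1):
        gk = xc[k:] @ xc[:-k] / n
        s += 2.0 * w[k - 1] * gk
    return float(max(s, 0.0))


def geweke_z(
    chain: np.ndarray, first_frac: float = 0.1, last_frac: float = 0.5
) -> float:
    """Geweke difference-of-means z-score with spectral variance estimates.

    Compares the mean of the first ``first_frac`` of the chain with the
    mean of the last ``last_frac``; a constant chain returns NaN (flagged
    "degenerate" rather than 0/0).
    """
    x = np.asarray(chain, float).ravel()
    if x.size < 50:
        raise ValueError(f"chain too short for Geweke diagnostic ({x.size} < 50)")
    na = max(int(first_frac * x.size), 2)
    nb = max(int(last_frac * x.size), 2)
    a, b = x[:na], x[-nb:]
    va = _spectral_variance(a) / na
    vb = _spectral_variance(b) / nb
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        return float("nan")
    return float((a.mean() - b.mean()) / denom)


def inefficiency_factor(chain: np.ndarray) -> float:
    """Inefficiency factor 1 + 2 * sum of Parzen-tapered autocorrelations.

    Values near 1 indicate i.i.d.-like mixing; an AR(1) chain with
    autocorrelation phi has asymptotic factor (1+phi)/(1-phi) (the tapered
    truncation shades this down for very persistent chains).
    """
    x = np.asarray(chain, float).ravel()
    if x.size < 100:
        raise ValueError(f"chain too short for inefficiency factor ({x.size} < 100)")
    xc = x - x.mean()
    gamma0 = xc @ xc / x.size
    if gamma0 == 0.0:
        return float("nan")
    K = max(int(4 * (x.size / 100.0) ** 0.25), 1)
    w = _parzen_weights(K)
    acf = np.array(
        [xc[k:] @ xc[:-k] / (x.size * gamma0) for k in range(1, K + 1)]
    )
    return float(max(1.0 + 2.0 * (w * acf).sum(), 0.0))


@dataclass
class PathSummary:
    """Pointwise posterior quantiles and mean of one latent path."""

    name: str
    mean: np.ndarray  # (T, d)
    quantiles: dict  # level -> (T, d)


def posterior_summary(draws, quantiles=(0.05, 0.5, 0.95)) -> dict[str, PathSummary]:
    """Pointwise mean and quantiles for each latent path in PosteriorDraws."""
    if draws.n_retained < 50:
        raise ValueError(
            f"need at least 50 retained draws, got {draws.n_retained}"
        )
    out = {}
    for name in ("b_path", "alpha_path", "sigma_path"):
        arr = getattr(draws, name)
        qs = np.quantile(arr, quantiles, axis=0)
        out[name] = PathSummary(
            name=name,
            mean=arr.mean(axis=0),
            quantiles={q: qs[i] for i, q in enumerate(quantiles)},
        )
    return out


@dataclass
class ConvergenceReport:
    """Geweke z-scores and inefficiency factors for a monitored subset.

    Monitored scalars are the time-averaged shock volatilities (one per
    equation) and the time-averaged own-first-lag coefficients.
    """

    geweke: dict = field(default_factory=dict)
    inefficiency: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @classmethod
    def from_draws(cls, draws) -> "ConvergenceReport":
        rep = cls()
        m = draws.dims.m
        sig = draws.sigma_path.mean(axis=1)  # (ndraw, m)
        for j in range(m):
            name = f"sigma_{j + 1}"
            rep._add(name, sig[:, j])
        own = [j * draws.dims.m + j for j in range(m)]  # first-lag diagonal
        bbar = draws.b_path.mean(axis=1)
        for j, pos in enumerate(own):
            rep._add(f"b_own_{j + 1}", bbar[:, pos])
        return rep

    def _add(self, name: str, chain: np.ndarray) -> None:
        if np.std(chain) == 0.0:
            self.geweke[name] = float("nan")
            self.inefficiency[name] = float("nan")
            self.flags.append(f"{name}: degenerate (constant chain)")
            return
        try:
            z = geweke_z(chain)
        except ValueError:
            z = float("nan")
            self.flags.append(f"{name}: chain too short for Geweke")
        try:
            eff = inefficiency_factor(chain)
        except ValueError:
            eff = float("nan")
        self.geweke[name] = z
        self.inefficiency[name] = eff
        if np.isfinite(z) and abs(z) > 3.0:
            self.flags.append(f"{name}: |Geweke z| = {abs(z):.2f} > 3")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "geweke": self.geweke,
                    "inefficiency": self.inefficiency,
                    "flags": self.flags,
                },
                fh,
                indent=2,
                default=float,
            )
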