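"""Synthetic quarterly datasets with the exact structure the model assumes.

The generator draws all three random-walk latent blocks (stacked VAR
coefficients B_t, lower-triangular elements alpha_t, log shock volatilities
log sigma_t), simulates the augmented vector y_t = [f_t', z_t', m_t]' from
the time-varying VAR, and projects a high-dimensional indicator panel off
it through the factor equation with AR + stochastic-volatility
idiosyncratic errors.  Full ground truth is retained so every downstream
stage (factor extraction, Gibbs estimation, impulse responses) can be
tested against known paths without any external data.

Scenario presets mirror the package's intended application setting: a national
sample of 98 indicator series over 74 quarters (2007Q1-2025Q2) with crisis
volatility windows at the 2008-, 2015- and 2020-analogue dates and a sign
switch in the uncertainty -> expenditure channel at the 2020-analogue
quarter, and a shorter pre-pandemic provincial sample (2009Q1-2019Q4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .irf import alpha_to_lower_triangular, build_companion, irf_surface_from_paths
from .quarters import quarter_labels

__all__ = [
    "StabilityError",
    "ScenarioConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_tvp_favar",
    "national_preset",
    "provincial_preset",
    "small_tvp_var_preset",
    "sign_switch_preset",
]

_MAX_STABILITY_RETRIES = 100


class StabilityError(RuntimeError):
    """The simulated coefficient paths kept producing an explosive VAR."""


@dataclass
class ScenarioConfig:
    """Everything that defines one synthetic scenario.

    Crisis windows are (start, end, multiplier) with 1-based inclusive
    quarter positions; the multiplier scales every shock standard deviation
    sigma_jt inside the window.  ``sign_switch_quarter`` (1-based, optional)
    is the date at which the uncertainty -> target coefficient ramps from
    ``epu_effect`` to ``-epu_effect`` over ``ramp_len`` quarters.
    """

    T: int = 74
    n: int = 98
    k: int = 3
    l: int = 2
    p: int = 2
    q: int = 1
    noise_scale: float = 1.0
    shock_scale: float = 0.5
    q_b_scale: float = 0.005
    q_a_scale: float = 0.02
    q_s_scale: float = 0.05
    crisis_windows: list = field(default_factory=list)
    sign_switch_quarter: int | None = None
    epu_effect: float = -0.25
    ramp_len: int = 4
    start: str = "2007Q1"
    irf_horizon: int = 12
    seed: int = 0

    @property
    def m(self) -> int:
        return self.k + self.l + 1

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("need at least one latent factor (k >= 1)")
        if self.m < 2:
            raise ValueError("augmented dimension k + l + 1 must be >= 2")
        if self.T <= self.p:
            raise ValueError("T must exceed the VAR lag order p")
        if self.l < 1:
            raise ValueError("need at least one core observable (the target)")
        for name in ("noise_scale", "shock_scale", "q_b_scale", "q_a_scale", "q_s_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for w in self.crisis_windows:
            s, e, mult = w
            if not (1 <= s <= e <= self.T):
                raise ValueError(f"crisis window {w} outside 1..T={self.T}")
            if mult <= 0:
                raise ValueError(f"crisis multiplier must be positive, got {mult}")
        if self.sign_switch_quarter is not None and not (
            1 <= self.sign_switch_quarter <= self.T
        ):
            raise ValueError("sign_switch_quarter outside 1..T")


@dataclass
class SyntheticTruth:
    """Ground-truth latent paths and derived quantities of one simulation."""

    factor_path: np.ndarray  # (T, k)
    lambda_f: np.ndarray  # (n, k)
    lambda_z: np.ndarray  # (n, l)
    lambda_m: np.ndarray  # (n, 1)
    rho: np.ndarray  # (n, q)
    b_path: np.ndarray  # (T, m^2 p)
    alpha_path: np.ndarray  # (T, m(m-1)/2)
    sigma_path: np.ndarray  # (T, m)
    h_path: np.ndarray  # (T, n) idiosyncratic log-volatilities
    omega_path: np.ndarray  # (T, m, m)
    true_irf: np.ndarray  # (T, H+1, m)

    def validate(self, m: int) -> None:
        """Check the triangular reconstruction Omega_t = (A^-1 S)(A^-1 S)'."""
        T = self.sigma_path.shape[0]
        for t in range(T):
            A = alpha_to_lower_triangular(self.alpha_path[t], m)
            impact = np.linalg.solve(A, np.diag(self.sigma_path[t]))
            omega = impact @ impact.T
            if not np.allclose(omega, self.omega_path[t], atol=1e-10):
                raise AssertionError(f"omega reconstruction fails at t={t}")
            if not np.allclose(
                self.omega_path[t], self.omega_path[t].T, atol=1e-12
            ):
                raise AssertionError(f"omega not symmetric at t={t}")
            np.linalg.cholesky(self.omega_path[t])


@dataclass
class SyntheticDataset:
    """A simulated study: observables plus the truth that generated them."""

    config: ScenarioConfig
    quarters: pd.PeriodIndex
    panel: pd.DataFrame  # (T, n) indicator panel x_it
    core: pd.DataFrame  # (T, l) core observables z_t (last column = target)
    epu: pd.Series  # (T,) uncertainty index m_t
    truth: SyntheticTruth

    @property
    def target(self) -> pd.Series:
        """The expenditure-like series: by convention the last core column."""
        return self.core.iloc[:, -1]

    @property
    def y(self) -> np.ndarray:
        """(T, m) true augmented vector [f, z, m]."""
        return np.hstack(
            [
                self.truth.factor_path,
                self.core.to_numpy(),
                self.epu.to_numpy()[:, None],
            ]
        )

    @property
    def var_names(self) -> list[str]:
        return (
            [f"f{j + 1}" for j in range(self.config.k)]
            + list(self.core.columns)
            + [str(self.epu.name)]
        )

    def factor_signal_share(self) -> float:
        """Mean share of panel variance carried by the common factors."""
        common = self.truth.factor_path @ self.truth.lambda_f.T
        return float(
            np.mean(common.var(axis=0) / self.panel.to_numpy().var(axis=0))
        )

    def to_csv(self, path) -> None:
        """Wide CSV: quarter label column plus one column per series."""
        df = pd.concat([self.panel, self.core, self.epu], axis=1)
        df.insert(0, "quarter", quarter_labels(self.quarters))
        df.to_csv(path, index=False, float_format="%.12g")

    def truth_to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for name in (
                "factor_path",
                "b_path",
                "alpha_path",
                "sigma_path",
                "h_path",
                "true_irf",
            ):
                fh.create_dataset(name, data=getattr(self.truth, name))
            fh.create_dataset("lambda_f", data=self.truth.lambda_f)
            fh.create_dataset("lambda_z", data=self.truth.lambda_z)
            fh.create_dataset("lambda_m", data=self.truth.lambda_m)


def _draw_coefficient_path(config: ScenarioConfig, rng: np.random.Generator):
    """One candidate random-walk path of the stacked VAR coefficients."""
    m, p, T = config.m, config.p, config.T
    mb = m * m * p
    target_ix = config.k + config.l - 1
    epu_ix = m - 1
    b1 = np.diag(rng.uniform(0.3, 0.6, m))
    b1 += rng.normal(0.0, 0.05, (m, m)) * (1 - np.eye(m))
    b1[target_ix, epu_ix] = config.epu_effect
    blocks = [b1]
    for lag in range(2, p + 1):
        blocks.append(rng.normal(0.0, 0.05 / lag**2, (m, m)))
    b0 = np.concatenate([blk.ravel(order="F") for blk in blocks])
    steps = rng.normal(0.0, config.q_b_scale, (T, mb))
    steps[0] = 0.0
    b_path = b0 + np.cumsum(steps, axis=0)
    if config.sign_switch_quarter is not None:
        # deterministic ramp flipping the uncertainty -> target channel
        pos = (epu_ix * m + target_ix)  # column-major position in vec(b1)
        ramp = np.zeros(T)
        s = config.sign_switch_quarter - 1
        L = max(config.ramp_len, 1)
        for t in range(T):
            if t < s:
                ramp[t] = 0.0
            elif t >= s + L:
                ramp[t] = -2.0 * config.epu_effect
            else:
                ramp[t] = -2.0 * config.epu_effect * (t - s + 1) / L
        b_path[:, pos] += ramp
    return b_path


def _max_companion_eig(b_path: np.ndarray, m: int, p: int) -> float:
    worst = 0.0
    for t in range(b_path.shape[0]):
        C = build_companion(b_path[t], m, p)
        worst = max(worst, float(np.max(np.abs(np.linalg.eigvals(C)))))
    return worst


def simulate_tvp_favar(config: ScenarioConfig) -> SyntheticDataset:
    """Simulate one full dataset with ground truth.

    Identical config (including seed) yields a bit-identical dataset.
    Coefficient paths are rejection-sampled for stability (every companion
    eigenvalue below 0.999); persistent failure raises
    :class:`StabilityError` with the worst eigenvalue seen.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m, p, T, n, k, l = config.m, config.p, config.T, config.n, config.k, config.l
    worst = np.inf
    b_path = None
    for _ in range(_MAX_STABILITY_RETRIES):
        candidate = _draw_coefficient_path(config, rng)
        worst = _max_companion_eig(candidate, m, p)
        if worst < 0.999:
            b_path = candidate
            break
    if b_path is None:
        raise StabilityError(
            f"no stable coefficient path in {_MAX_STABILITY_RETRIES} tries; "
            f"last max companion eigenvalue {worst:.4f} (>= 0.999). "
            "Reduce q_b_scale or the base coefficient magnitudes."
        )

    na = m * (m - 1) // 2
    alpha0 = rng.normal(0.0, 0.2, na)
    a_steps = rng.normal(0.0, config.q_a_scale, (T, na))
    a_steps[0] = 0.0
    alpha_path = alpha0 + np.cumsum(a_steps, axis=0)

    logsig0 = np.log(config.shock_scale) + rng.normal(0.0, 0.1, m)
    s_steps = rng.normal(0.0, config.q_s_scale, (T, m))
    s_steps[0] = 0.0
    logsig = logsig0 + np.cumsum(s_steps, axis=0)
    sigma_path = np.exp(logsig)
    for s, e, mult in config.crisis_windows:
        sigma_path[s - 1 : e, :] *= mult

    # reduced-form covariances and the VAR simulation
    omega_path = np.empty((T, m, m))
    impacts = np.empty((T, m, m))
    for t in range(T):
        A = alpha_to_lower_triangular(alpha_path[t], m)
        impacts[t] = np.linalg.solve(A, np.diag(sigma_path[t]))
        omega_path[t] = impacts[t] @ impacts[t].T

    burn = 20
    lags = np.zeros((p, m))
    # settle the lag window under the initial-period parameters
    C0_blocks = [
        b_path[0][lag * m * m : (lag + 1) * m * m].reshape((m, m), order="F")
        for lag in range(p)
    ]
    for _ in range(burn):
        shock = impacts[0] @ rng.standard_normal(m)
        ynew = sum(C0_blocks[i] @ lags[i] for i in range(p)) + shock
        lags = np.vstack([ynew, lags[:-1]])
    y = np.empty((T, m))
    for t in range(T):
        blocks = [
            b_path[t][lag * m * m : (lag + 1) * m * m].reshape((m, m), order="F")
            for lag in range(p)
        ]
        shock = impacts[t] @ rng.standard_normal(m)
        y[t] = sum(blocks[i] @ lags[i] for i in range(p)) + shock
        lags = np.vstack([y[t], lags[:-1]])

    f = y[:, :k]
    z = y[:, k : k + l]
    epu = y[:, -1]

    # factor-equation panel; loadings are calibrated by each factor's
    # realized scale so every factor carries a unit-variance common
    # component regardless of the VAR dynamics the path happened to draw
    lambda_f = rng.normal(0.0, 1.0, (n, k)) / f.std(axis=0)
    lambda_z = np.zeros((n, l))
    lambda_m = np.zeros((n, 1))
    mask_z = rng.random(n) < 0.25
    mask_m = rng.random(n) < 0.25
    lambda_z[mask_z] = rng.normal(0.0, 0.3, (int(mask_z.sum()), l))
    lambda_m[mask_m] = rng.normal(0.0, 0.3, (int(mask_m.sum()), 1))

    q_ord = config.q
    if q_ord > 0:
        raw = rng.uniform(0.2, 0.6, (n, q_ord))
        scale = np.maximum(1.0, raw.sum(axis=1) / 0.9)
        rho = raw / scale[:, None]
    else:
        rho = np.empty((n, 0))
    h0 = np.log(max(config.noise_scale, 1e-8)) + rng.normal(0.0, 0.1, n)
    h_steps = rng.normal(0.0, config.q_s_scale, (T, n))
    h_steps[0] = 0.0
    h_path = h0 + np.cumsum(h_steps, axis=0)

    eps = np.exp(h_path) * rng.standard_normal((T, n))
    u = np.zeros((T, n))
    ulags = np.zeros((max(q_ord, 1), n))
    for _ in range(burn):
        e0 = np.exp(h_path[0]) * rng.standard_normal(n)
        unew = e0
        for j in range(q_ord):
            unew = unew + rho[:, j] * ulags[j]
        ulags = np.vstack([unew, ulags[:-1]]) if q_ord > 0 else ulags
    for t in range(T):
        unew = eps[t].copy()
        for j in range(q_ord):
            unew += rho[:, j] * ulags[j]
        u[t] = unew
        if q_ord > 0:
            ulags = np.vstack([u[t], ulags[:-1]])

    x = f @ lambda_f.T + z @ lambda_z.T + epu[:, None] @ lambda_m.T + u

    true_irf = irf_surface_from_paths(
        b_path, alpha_path, sigma_path, m - 1, config.irf_horizon, m, p
    )

    quarters = _span(config)
    panel_cols = [f"x{i + 1:03d}" for i in range(n)]
    core_cols = [f"z{j + 1}" for j in range(l - 1)] + ["health_exp"]
    truth = SyntheticTruth(
        factor_path=f,
        lambda_f=lambda_f,
        lambda_z=lambda_z,
        lambda_m=lambda_m,
        rho=rho,
        b_path=b_path,
        alpha_path=alpha_path,
        sigma_path=sigma_path,
        h_path=h_path,
        omega_path=omega_path,
        true_irf=true_irf,
    )
    return SyntheticDataset(
        config=config,
        quarters=quarters,
        panel=pd.DataFrame(x, columns=panel_cols),
        core=pd.DataFrame(z, columns=core_cols),
        epu=pd.Series(epu, name="epu"),
        truth=truth,
    )


def _span(config: ScenarioConfig) -> pd.PeriodIndex:
    start = pd.Period(config.start, freq="Q-DEC")
    return pd.period_range(start, periods=config.T, freq="Q-DEC")


def _quarter_pos(start: str, label: str) -> int:
    """1-based position of ``label`` in a grid starting at ``start``."""
    p0 = pd.Period(start, freq="Q-DEC")
    p1 = pd.Period(label, freq="Q-DEC")
    return int(p1.ordinal - p0.ordinal) + 1


def national_preset(seed: int = 0) -> ScenarioConfig:
    """The national-sample scenario: 98 series, 3 factors, 2007Q1-2025Q2.

    Crisis volatility windows sit at the 2008-, 2015- and 2020-analogue
    dates; the uncertainty -> expenditure coefficient switches sign at the
    2020-analogue quarter (contractionary before, expansionary after).
    """
    start = "2007Q1"
    cfg = ScenarioConfig(
        T=74,
        n=98,
        k=3,
        l=2,
        start=start,
        seed=seed,
        crisis_windows=[
            (_quarter_pos(start, "2008Q3"), _quarter_pos(start, "2009Q2"), 3.0),
            (_quarter_pos(start, "2015Q3"), _quarter_pos(start, "2016Q2"), 2.0),
            (_quarter_pos(start, "2020Q1"), _quarter_pos(start, "2020Q4"), 4.0),
        ],
        sign_switch_quarter=_quarter_pos(start, "2020Q1"),
    )
    cfg.validate()
    return cfg


def provincial_preset(seed: int = 0) -> ScenarioConfig:
    """The provincial-sample scenario: 2009Q1-2019Q4 (pre-pandemic), smaller panel."""
    start = "2009Q1"
    cfg = ScenarioConfig(
        T=44,
        n=30,
        k=3,
        l=2,
        start=start,
        seed=seed,
        crisis_windows=[
            (_quarter_pos(start, "2015Q3"), _quarter_pos(start, "2016Q2"), 2.0),
        ],
        sign_switch_quarter=None,
    )
    cfg.validate()
    return cfg


def small_tvp_var_preset(T: int = 80, seed: int = 0) -> ScenarioConfig:
    """A small three-variable TVP-VAR with SV for recovery studies (m=3, p=1)."""
    return ScenarioConfig(
        T=T,
        n=6,
        k=1,
        l=1,
        p=1,
        q=0,
        seed=seed,
        start="2007Q1",
        crisis_windows=[],
        sign_switch_quarter=None,
    )


def sign_switch_preset(T: int = 200, seed: int = 0) -> ScenarioConfig:
    """Three-variable scenario whose uncertainty -> target channel flips sign mid-sample."""
    return ScenarioConfig(
        T=T,
        n=6,
        k=1,
        l=1,
        p=1,
        q=0,
        seed=seed,
        start="2007Q1",
        q_b_scale=0.003,
        crisis_windows=[],
        sign_switch_quarter=T // 2,
        epu_effect=-0.25,
    )
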