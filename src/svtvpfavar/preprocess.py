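"""Data preparation for the quarterly macro panel.

The pipeline applied to every raw series before modelling:

1. alignment of mixed-frequency data to one value per quarter (mean, sum or
   last observation within the quarter),
2. seasonal adjustment by regression on quarter-of-year dummies (the
   adjusted series keeps the original overall mean),
3. an augmented Dickey-Fuller screen with iterative differencing until the
   unit-root null is rejected,
4. column standardization to zero mean / unit sample variance ahead of
   principal-component factor extraction.

Each step records what it did in a :class:`TransformRecord` so the whole
transformation is reportable and, where invertible, reversible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "NonStationaryError",
    "TransformRecord",
    "PreprocessReport",
    "align_to_quarterly",
    "seasonal_adjust",
    "adf_test",
    "difference_until_stationary",
    "standardize",
    "destandardize",
    "preprocess_panel",
]


class NonStationaryError(RuntimeError):
    """A series failed to reach stationarity within the differencing budget."""


@dataclass
class TransformRecord:
    """Per-series log of the transformations applied."""

    series_name: str
    aggregation: str = "none"
    seasonal_adjusted: bool = False
    diff_order: int = 0
    standardized: bool = False
    mean: float = 0.0
    std: float = 1.0
    adf_statistic: float = float("nan")
    stationary: bool = False


@dataclass
class PreprocessReport:
    """Transformation records and ADF decisions for a whole panel."""

    level: float
    max_d: int
    lag_order: int
    records: list[TransformRecord] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "level": self.level,
            "max_d": self.max_d,
            "lag_order": self.lag_order,
            "records": [asdict(r) for r in self.records],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PreprocessReport":
        with open(path) as fh:
            payload = json.load(fh)
        rep = cls(payload["level"], payload["max_d"], payload["lag_order"])
        rep.records = [TransformRecord(**r) for r in payload["records"]]
        return rep


def align_to_quarterly(series: pd.Series, method: str = "mean") -> pd.Series:
    """Aggregate a dated series to one value per quarter.

    ``series`` must carry a DatetimeIndex or PeriodIndex at monthly or
    quarterly frequency.  Quarters spanned by the index but without any
    observation come back as NaN.
    """
    if method not in ("mean", "sum", "last"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if len(series) == 0:
        raise ValueError("empty input series")
    idx = series.index
    if isinstance(idx, pd.PeriodIndex):
        periods = idx.asfreq("Q-DEC")
    else:
        periods = pd.DatetimeIndex(idx).to_period("Q-DEC")
    grouped = series.groupby(periods)
    out = getattr(grouped, method)()
    full = pd.period_range(periods.min(), periods.max(), freq="Q-DEC")
    return out.reindex(full)


def seasonal_adjust(series: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Remove quarter-of-year means estimated by dummy regression.

    Equivalent to subtracting each quarter-of-year's mean deviation from the
    overall mean, so the output mean equals the input mean.  Requires at
    least two full years of data and a quarterly position for every value:
    a pandas Series with a quarterly PeriodIndex uses calendar quarters,
    a bare array assumes the first value is a Q1.
    """
    values = np.asarray(series, float)
    if values.ndim != 1:
        raise ValueError("seasonal_adjust expects a single series")
    if values.size < 8:
        raise ValueError(
            f"need at least 8 quarterly observations, got {values.size}"
        )
    if isinstance(series, pd.Series) and isinstance(series.index, pd.PeriodIndex):
        qpos = series.index.quarter.to_numpy()
    else:
        qpos = (np.arange(values.size) % 4) + 1
    overall = values.mean()
    adjusted = values.copy()
    for q in (1, 2, 3, 4):
        mask = qpos == q
        if mask.any():
            adjusted[mask] -= values[mask].mean() - overall
    if isinstance(series, pd.Series):
        return pd.Series(adjusted, index=series.index, name=series.name)
    return adjusted


def adf_test(
    series: np.ndarray, lag_order: int = 4, level: float = 0.05
) -> tuple[float, bool]:
    """Augmented Dickey-Fuller unit-root test (intercept, no trend).

    Returns ``(statistic, reject_unit_root)`` where the statistic is the
    t-ratio on the lagged level and the decision compares it with the
    MacKinnon critical value at ``level``.
    """
    x = np.asarray(series, float).ravel()
    x = x[~np.isnan(x)]
    if level not in (0.01, 0.05, 0.10):
        raise ValueError("level must be one of 0.01, 0.05, 0.10")
    if x.size <= lag_order + 10:
        raise ValueError(
            f"series too short ({x.size}) for lag order {lag_order}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.std(x) == 0.0:
        raise ValueError("degenerate regression: constant series")
    stat, _, _, _, crit = adfuller(x, maxlag=lag_order, regression="c", autolag=None)
    key = {0.01: "1%", 0.05: "5%", 0.10: "10%"}[level]
    return float(stat), bool(stat < crit[key])


def difference_until_stationary(
    series: np.ndarray,
    max_d: int = 2,
    level: float = 0.05,
    lag_order: int = 4,
    name: str = "series",
) -> tuple[np.ndarray, int, float]:
    """Difference a series until the ADF test rejects the unit root.

    Returns ``(transformed, d, statistic)`` for the smallest d <= max_d at
    which the test rejects; raises :class:`NonStationaryError` otherwise.
    """
    if max_d < 0:
        raise ValueError("max_d must be >= 0")
    x = np.asarray(series, float).ravel()
    for d in range(max_d + 1):
        y = np.diff(x, n=d) if d else x
        stat, reject = adf_test(y, lag_order=lag_order, level=level)
        if reject:
            return y, d, stat
    raise NonStationaryError(
        f"{name!r} still non-stationary after {max_d} difference(s) "
        f"(last ADF statistic {stat:.3f} at level {level})"
    )


def standardize(panel: pd.DataFrame | np.ndarray):
    """Column z-scores with sample std (ddof=1).

    Returns ``(standardized, means, stds)``; raises on constant columns.
    """
    df = pd.DataFrame(panel).copy()
    means = df.mean(axis=0)
    stds = df.std(axis=0, ddof=1)
    bad = stds[stds == 0.0].index.tolist()
    if bad:
        raise ValueError(f"zero-variance column(s): {bad}")
    out = (df - means) / stds
    if isinstance(panel, np.ndarray):
        return out.to_numpy(), means.to_numpy(), stds.to_numpy()
    return out, means, stds


def destandardize(panel, means, stds):
    """Inverse of :func:`standardize`."""
    return pd.DataFrame(panel) * np.asarray(stds) + np.asarray(means)


def preprocess_panel(
    df: pd.DataFrame,
    level: float = 0.05,
    max_d: int = 2,
    lag_order: int = 4,
    seasonal: bool = True,
    do_standardize: bool = True,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full preparation of a wide quarterly panel.

    Every column is (optionally) seasonally adjusted, differenced to
    stationarity at ``level`` and standardized.  Columns are differenced
    individually; to keep the output rectangular all columns are trimmed to
    a common sample that drops the first ``max(d)`` rows.

    Returns the prepared panel and a :class:`PreprocessReport`.
    """
    report = PreprocessReport(level=level, max_d=max_d, lag_order=lag_order)
    transformed: dict[str, np.ndarray] = {}
    orders: dict[str, int] = {}
    for name in df.columns:
        rec = TransformRecord(series_name=str(name))
        x = df[name].to_numpy(float)
        if seasonal:
            series = pd.Series(x, index=df.index) if isinstance(
                df.index, pd.PeriodIndex
            ) else x
            x = np.asarray(seasonal_adjust(series), float)
            rec.seasonal_adjusted = True
        y, d, stat = difference_until_stationary(
            x, max_d=max_d, level=level, lag_order=lag_order, name=str(name)
        )
        rec.diff_order = d
        rec.adf_statistic = stat
        rec.stationary = True
        transformed[str(name)] = y
        orders[str(name)] = d
        report.records.append(rec)
    d_max = max(orders.values(), default=0)
    T_out = len(df) - d_max
    aligned = {
        name: series[len(series) - T_out :] for name, series in transformed.items()
    }
    out = pd.DataFrame(aligned, index=df.index[len(df) - T_out :])
    if do_standardize:
        out, means, stds = standardize(out)
        for rec in report.records:
            rec.standardized = True
            rec.mean = float(means[rec.series_name])
            rec.std = float(stds[rec.series_name])
    return out, report
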