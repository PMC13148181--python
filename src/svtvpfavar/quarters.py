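"""Quarterly calendar utilities.

All series handled by this package live on a contiguous quarterly grid with
labels rendered as ``YYYYQq`` (e.g. ``2007Q1``).  Internally quarters are
:class:`pandas.Period` objects with quarterly frequency; these helpers only
add strict label validation and contiguity checks on top of pandas.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = [
    "QuarterParseError",
    "QuarterOrderError",
    "parse_quarter",
    "enumerate_quarters",
    "quarter_labels",
    "check_contiguous",
]

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


class QuarterParseError(ValueError):
    """A quarter label does not match the ``YYYYQq`` format."""


class QuarterOrderError(ValueError):
    """A quarter range was requested with start after end."""


def parse_quarter(label: str) -> pd.Period:
    """Parse a strict ``YYYYQq`` label into a quarterly :class:`pandas.Period`."""
    if not isinstance(label, str):
        raise QuarterParseError(f"quarter label must be a string, got {label!r}")
    match = _QUARTER_RE.match(label.strip())
    if match is None:
        raise QuarterParseError(
            f"malformed quarter label {label!r}; expected 'YYYYQq' with q in 1..4"
        )
    year, q = int(match.group(1)), int(match.group(2))
    return pd.Period(year=year, quarter=q, freq="Q-DEC")


def enumerate_quarters(start: str, end: str) -> pd.PeriodIndex:
    """Every quarter from ``start`` to ``end`` inclusive, in calendar order.

    Parameters
    ----------
    start, end : str
        Quarter labels in ``YYYYQq`` form, ``start <= end``.

    Returns
    -------
    pandas.PeriodIndex
        Contiguous quarterly index; e.g. ``("2007Q1", "2025Q2")`` spans 74
        quarters.
    """
    p0, p1 = parse_quarter(start), parse_quarter(end)
    if p0 > p1:
        raise QuarterOrderError(f"start quarter {start!r} is after end quarter {end!r}")
    return pd.period_range(p0, p1, freq="Q-DEC")


def quarter_labels(index: pd.PeriodIndex) -> list[str]:
    """Render a quarterly PeriodIndex as ``YYYYQq`` strings."""
    return [f"{p.year}Q{p.quarter}" for p in index]


def check_contiguous(index: pd.PeriodIndex) -> None:
    """Raise ``ValueError`` unless ``index`` is strictly increasing with no gaps."""
    if len(index) == 0:
        raise ValueError("empty quarter index")
    diffs = index[1:].asi8 - index[:-1].asi8
    if len(diffs) and not (diffs == 1).all():
        raise ValueError("quarter index is not contiguous and strictly increasing")
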