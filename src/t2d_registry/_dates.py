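"""Calendar-date helpers shared across the package.

All dates in the package are whole calendar days (pandas ``datetime64[ns]``
at midnight); intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def add_years(dates, years: int) -> pd.Series:
    """Shift dates by a whole number of calendar years.

    Feb 29 anniversaries falling in a non-leap year resolve to Mar 1 (the
    first day on which the full year has elapsed under half-open-interval
    semantics). NaT propagates.
    """
    s = pd.Series(pd.to_datetime(dates))
    parts = pd.DataFrame(
        {"year": s.dt.year + years, "month": s.dt.month, "day": s.dt.day}
    )
    out = pd.to_datetime(parts, errors="coerce")
    bad = out.isna() & s.notna()
    if bad.any():
        parts.loc[bad, "month"] = 3
        parts.loc[bad, "day"] = 1
        out = pd.to_datetime(parts, errors="coerce")
    out.index = s.index
    return out


def year_start(years) -> pd.Series:
    """January 1 of each given calendar year (vectorised)."""
    y = np.asarray(years, dtype=float)
    frame = pd.DataFrame({"year": y, "month": 1, "day": 1})
    return pd.to_datetime(frame, errors="coerce")


def to_days(delta) -> np.ndarray:
    """Timedelta-like -> integer day counts."""
    return (pd.Series(delta) / pd.Timedelta(days=1)).to_numpy()
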