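"""Phenological composite calendar.

Winter-to-spring phytoplankton blooms in the Mediterranean straddle the
turn of the civil year, so all seasonal analysis here runs on a
*phenological year* anchored at 1 August: day 1 of the cycle is 1 August
and the cycle is divided into 52 consecutive 7-day composites.  Days
beyond 7 x 52 = 364 (day 365, and 366 in leap years) are folded into
composite 52, which keeps composite 1 aligned with 1 August every year.

Composite ("bin") indices run from 1 to 52 inclusive.
"""

from __future__ import annotations

import datetime as _dt
import re

import numpy as np
import pandas as pd

N_BINS = 52
#: reference (non-leap) cycle used to render composite labels as dates
_REF_START = _dt.date(2001, 8, 1)

__all__ = [
    "N_BINS",
    "phenological_year",
    "day_of_cycle",
    "composite_index",
    "composite_index_series",
    "circular_bin_distance",
    "bins_between",
    "render_week_label",
    "parse_week_label",
]


def phenological_year(date: _dt.date) -> int:
    """Calendar year in which the phenological year containing ``date`` begins.

    The phenological year starting 1 August 2005 covers 2005-08-01 to
    2006-07-31 and is labelled 2005.
    """
    return date.year if date.month >= 8 else date.year - 1


def day_of_cycle(date: _dt.date) -> int:
    """1-based day number within the Aug-anchored phenological year."""
    start = _dt.date(phenological_year(date), 8, 1)
    return (date - start).days + 1


def composite_index(date) -> int:
    """Map a calendar date to its 7-day composite index in 1..52.

    bin = floor((day_of_cycle - 1) / 7) + 1, capped at 52 so that the
    last composite absorbs day 365 (and 366 in leap years).
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    elif isinstance(date, (pd.Timestamp, _dt.datetime)):
        date = date.date() if hasattr(date, "date") else date
    return min((day_of_cycle(date) - 1) // 7 + 1, N_BINS)


def composite_index_series(dates) -> np.ndarray:
    """Vectorised :func:`composite_index` for a DatetimeIndex / date array."""
    idx = pd.DatetimeIndex(dates)
    pheno_year = np.where(idx.month >= 8, idx.year, idx.year - 1)
    starts = pd.to_datetime({"year": pheno_year, "month": 8, "day": 1})
    doy = (idx - pd.DatetimeIndex(starts)).days + 1
    return np.minimum((doy - 1) // 7 + 1, N_BINS).astype(int)


def circular_bin_distance(a: int, b: int) -> int:
    """Shortest circular distance between two composite indices."""
    d = abs(int(a) - int(b)) % N_BINS
    return min(d, N_BINS - d)


def bins_between(start_bin: int, end_bin: int) -> int:
    """Inclusive number of composites from ``start_bin`` to ``end_bin``,
    counting forward circularly (bins (k, k) -> 1)."""
    return (int(end_bin) - int(start_bin)) % N_BINS + 1


def _cycle_date(doc: int) -> _dt.date:
    """Calendar date of cycle day ``doc`` in the reference (non-leap) year."""
    return _REF_START + _dt.timedelta(days=int(doc) - 1)


def _fmt(d0: _dt.date, d1: _dt.date) -> str:
    if d0.month == d1.month:
        return f"{d0.day:02d}–{d1.day:02d} {d0.strftime('%b')}"
    return f"{d0.day:02d} {d0.strftime('%b')}–{d1.day:02d} {d1.strftime('%b')}"


def render_week_label(bin_index: int, style: str = "onset") -> str:
    """Render a composite index as a calendar date range (e.g. ``07–13 Nov``).

    Two rendering conventions are in use in regional phenology tables:

    * ``"onset"`` — the composite's own span, cycle days 7(b-1)+1 .. 7(b-1)+7
      (used for initiation and peak weeks);
    * ``"end"`` — a span starting on the composite's final day, cycle days
      7b .. 7b+6 (used for termination weeks).

    With these conventions the printed initiation/termination ranges of the
    published Eastern-Mediterranean atlas are reproduced exactly together
    with duration = 7 x inclusive composite count.
    """
    b = int(bin_index)
    if not 1 <= b <= N_BINS:
        raise ValueError(f"composite index must be in 1..{N_BINS}, got {b}")
    if style == "onset":
        start = 7 * (b - 1) + 1
    elif style == "end":
        start = 7 * b
    else:
        raise ValueError(f"unknown label style {style!r}")
    return _fmt(_cycle_date(start), _cycle_date(start + 6))


_MONTHS = {m[:3].lower(): i for i, m in enumerate(
    ["January", "February", "March", "April", "May", "June", "July",
     "August", "September", "October", "November", "December"], start=1)}

_LABEL_RE = re.compile(
    r"^\s*(\d{1,2})\s*([A-Za-z]*)\s*[–—-]\s*(\d{1,2})\s*([A-Za-z]+)\s*$")


def parse_week_label(label: str, style: str = "onset") -> int:
    """Invert :func:`render_week_label`: a printed week label -> composite index.

    Accepts ``"07–13 Nov"`` and cross-month forms such as ``"26 Mar–01 Apr"``;
    month names may be abbreviated or spelled out.  Raises ``ValueError`` if
    the label's start day is not on the grid implied by ``style``.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable week label {label!r}")
    day0, mon0, _day1, mon1 = m.groups()
    month0 = _MONTHS[(mon0 or mon1)[:3].lower()]
    d0 = _dt.date(2001 if month0 >= 8 else 2002, month0, int(day0))
    doc = (d0 - _REF_START).days + 1
    if style == "onset":
        if (doc - 1) % 7:
            raise ValueError(f"label {label!r} does not start a composite")
        return (doc - 1) // 7 + 1
    if style == "end":
        if doc % 7:
            raise ValueError(f"label {label!r} does not start on day 7k")
        return doc // 7
    raise ValueError(f"unknown label style {style!r}")
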