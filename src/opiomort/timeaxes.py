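"""Calendar machinery shared by the registry simulator and the Lexis engine.

All follow-up splitting in this package happens on three timescales:

* calendar period — six three-year bins, 2001–03 … 2016–18;
* current age — single completed years, cut at each birthday;
* time since cohort entry — three-year bands, cut at each third anniversary.

Dates are handled at day resolution throughout.  Intervals are half-open
``[start, end)``: a cut falling on the last day of follow-up produces no
zero-length cell.  A Feb-29 birthday (or anniversary) falls on Mar 1 in
non-leap years.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

STUDY_START = dt.date(2001, 1, 1)
ADMIN_END = dt.date(2018, 10, 30)  # six months before the death-data horizon

#: Ordered labels of the six calendar-period bins.
PERIOD_LABELS = ("2001-03", "2004-06", "2007-09", "2010-12", "2013-15", "2016-18")
#: First day of each period bin.
PERIOD_STARTS = tuple(dt.date(2001 + 3 * i, 1, 1) for i in range(6))

DAYS_PER_YEAR = 365.25
WASHOUT_DAYS = 365  # "12 months" of registration washout, as exact days

__all__ = [
    "STUDY_START",
    "ADMIN_END",
    "PERIOD_LABELS",
    "PERIOD_STARTS",
    "DAYS_PER_YEAR",
    "WASHOUT_DAYS",
    "period_label",
    "add_years",
    "anniversary_in_year",
    "completed_years",
    "split_followup",
]


def _is_leap(year: np.ndarray) -> np.ndarray:
    year = np.asarray(year)
    return ((year % 4 == 0) & (year % 100 != 0)) | (year % 400 == 0)


def _build_dates(year, month, day) -> pd.Series:
    """Assemble datetime64 values from component arrays, Feb-29 -> Mar 1."""
    year = np.asarray(year, dtype=np.int64)
    month = np.asarray(month, dtype=np.int64)
    day = np.asarray(day, dtype=np.int64)
    feb29 = (month == 2) & (day == 29) & ~_is_leap(year)
    month = np.where(feb29, 3, month)
    day = np.where(feb29, 1, day)
    return pd.to_datetime(pd.DataFrame({"year": year, "month": month, "day": day}))


def period_label(dates) -> np.ndarray:
    """Calendar-period bin label for each date (dates must lie in 2001–2018)."""
    years = pd.DatetimeIndex(pd.to_datetime(dates)).year.to_numpy()
    idx = (years - 2001) // 3
    if (idx < 0).any() or (idx >= len(PERIOD_LABELS)).any():
        raise ValueError("date outside the 2001-2018 study window")
    return np.asarray(PERIOD_LABELS, dtype=object)[idx]


def add_years(dates, n: int) -> pd.Series:
    """Shift dates by whole calendar years; Feb 29 maps to Mar 1 off-leap."""
    ts = pd.DatetimeIndex(pd.to_datetime(dates))
    return _build_dates(ts.year + n, ts.month, ts.day)


def anniversary_in_year(origin, year) -> pd.Series:
    """The anniversary of each ``origin`` date falling in calendar ``year``."""
    ts = pd.DatetimeIndex(pd.to_datetime(origin))
    year = np.broadcast_to(np.asarray(year, dtype=np.int64), ts.shape)
    return _build_dates(year, ts.month, ts.day)


def completed_years(origin, at) -> np.ndarray:
    """Completed years elapsed from ``origin`` to ``at`` (element-wise).

    Uses calendar anniversaries, so a person is ``k`` years old from their
    k-th birthday (inclusive) to the day before the next one.
    """
    o = pd.DatetimeIndex(pd.to_datetime(origin))
    a = pd.DatetimeIndex(pd.to_datetime(at))
    ann = pd.DatetimeIndex(anniversary_in_year(o, a.year))
    return (a.year - o.year - (a < ann).astype(np.int64)).to_numpy()


def _collect_cuts(start_d, stop_d, cand) -> tuple[np.ndarray, np.ndarray]:
    """Indices and day-numbers of candidate cuts strictly inside (start, stop)."""
    cand_d = pd.DatetimeIndex(cand).to_numpy().astype("datetime64[D]").astype(np.int64)
    mask = (cand_d > start_d) & (cand_d < stop_d)
    return np.nonzero(mask)[0], cand_d[mask]


def split_followup(
    start,
    stop,
    birth,
    tse_origin=None,
    extra_cuts: tuple = (),
) -> pd.DataFrame:
    """Split follow-up intervals at every timescale boundary.

    Parameters
    ----------
    start, stop, birth
        Aligned date-like arrays (one element per interval).  ``stop`` is
        exclusive.  Intervals with ``start >= stop`` are rejected.
    tse_origin
        If given, the cohort entry dates from which three-year
        time-since-entry anniversaries are cut and ``tse_band`` computed.
    extra_cuts
        Additional aligned date arrays (NaT allowed) inserted as cuts when
        they fall strictly inside the interval, e.g. an exposure-onset date.

    Returns
    -------
    DataFrame with columns ``idx`` (position in the input arrays), ``t0``,
    ``t1`` (datetime64 cell bounds), ``days`` (integer length), ``age_years``
    (completed years at ``t0``), ``period_bin`` and, when ``tse_origin`` is
    given, ``tse_band`` (completed three-year bands since entry).
    """
    start_ts = pd.DatetimeIndex(pd.to_datetime(start))
    stop_ts = pd.DatetimeIndex(pd.to_datetime(stop))
    birth_ts = pd.DatetimeIndex(pd.to_datetime(birth))
    n = len(start_ts)
    start_d = start_ts.to_numpy().astype("datetime64[D]").astype(np.int64)
    stop_d = stop_ts.to_numpy().astype("datetime64[D]").astype(np.int64)
    if (start_d >= stop_d).any():
        bad = int(np.argmax(start_d >= stop_d))
        raise ValueError(f"interval {bad}: start must precede stop")

    idx_parts = [np.arange(n)]
    day_parts = [start_d]

    years = np.arange(2001, 2019)
    for p in PERIOD_STARTS[1:]:
        pd_day = np.int64(np.datetime64(p, "D").astype(np.int64))
        mask = (start_d < pd_day) & (pd_day < stop_d)
        idx_parts.append(np.nonzero(mask)[0])
        day_parts.append(np.full(mask.sum(), pd_day))
    for y in years:
        i, d = _collect_cuts(start_d, stop_d, anniversary_in_year(birth_ts, y))
        idx_parts.append(i)
        day_parts.append(d)
    if tse_origin is not None:
        origin_ts = pd.DatetimeIndex(pd.to_datetime(tse_origin))
        for k in range(1, 7):  # 3k-year anniversaries within an 18-year study
            i, d = _collect_cuts(start_d, stop_d, add_years(origin_ts, 3 * k))
            idx_parts.append(i)
            day_parts.append(d)
    for cuts in extra_cuts:
        cand = pd.DatetimeIndex(pd.to_datetime(cuts))
        cand_d = cand.to_numpy().astype("datetime64[D]").astype(np.float64)
        mask = (cand_d > start_d) & (cand_d < stop_d)  # NaT compares False
        idx_parts.append(np.nonzero(mask)[0])
        day_parts.append(cand_d[mask].astype(np.int64))

    idx = np.concatenate(idx_parts)
    day = np.concatenate(day_parts)
    order = np.lexsort((day, idx))
    idx, day = idx[order], day[order]
    keep = np.ones(len(idx), dtype=bool)  # drop coincident cuts
    keep[1:] = (idx[1:] != idx[:-1]) | (day[1:] != day[:-1])
    idx, day = idx[keep], day[keep]

    t1 = np.empty_like(day)
    last = np.ones(len(idx), dtype=bool)
    last[:-1] = idx[:-1] != idx[1:]
    t1[~last] = day[1:][~last[:-1]] if len(day) > 1 else 0
    t1[last] = stop_d[idx[last]]

    t0_dt = day.astype("datetime64[D]")
    cells = pd.DataFrame(
        {
            "idx": idx,
            "t0": t0_dt.astype("datetime64[ns]"),
            "t1": t1.astype("datetime64[D]").astype("datetime64[ns]"),
            "days": t1 - day,
        }
    )
    cells["age_years"] = completed_years(birth_ts[idx], cells["t0"])
    cells["period_bin"] = period_label(cells["t0"])
    if tse_origin is not None:
        tse_years = completed_years(origin_ts[idx], cells["t0"])
        cells["tse_band"] = tse_years // 3
    return cells
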