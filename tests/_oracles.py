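"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorised machinery: follow-up is
classified one day at a time with plain ``datetime`` arithmetic, so they are
slow but transparent.
"""

from __future__ import annotations

import datetime as dt

DAYS_PER_YEAR = 365.25


def day_period(day: dt.date) -> str:
    i = (day.year - 2001) // 3
    labels = ["2001-03", "2004-06", "2007-09", "2010-12", "2013-15", "2016-18"]
    return labels[i]


def anniversary(origin: dt.date, year: int) -> dt.date:
    """Anniversary of origin in a given year; Feb 29 -> Mar 1 off-leap."""
    try:
        return origin.replace(year=year)
    except ValueError:
        return dt.date(year, 3, 1)


def completed_years(origin: dt.date, day: dt.date) -> int:
    years = day.year - origin.year
    if day < anniversary(origin, day.year):
        years -= 1
    return years


def walk_days(entry: dt.date, exit_: dt.date, birth: dt.date):
    """Yield (day, period_label, age_years, tse_band) for each follow-up day."""
    day = entry
    while day < exit_:
        yield (
            day,
            day_period(day),
            completed_years(birth, day),
            completed_years(entry, day) // 3,
        )
        day += dt.timedelta(days=1)


def aggregate_cells(entry, exit_, birth):
    """Day-walk aggregation into (period, age, tse) -> day counts."""
    counts: dict = {}
    for _, period, age, tse in walk_days(entry, exit_, birth):
        key = (period, age, tse)
        counts[key] = counts.get(key, 0) + 1
    return counts


def expected_deaths_daywalk(people, rate_lookup, band_width=5):
    """Expected deaths by walking each exposed person's follow-up day by day.

    ``people``: iterable of (entry, exit, birth, sex); ``rate_lookup``:
    (age_band, sex, period) -> rate per person-year (missing -> 0).
    """
    total = 0.0
    for entry, exit_, birth, sex in people:
        for _, period, age, _ in walk_days(entry, exit_, birth):
            band = 18 + band_width * ((age - 18) // band_width)
            total += rate_lookup.get((band, sex, period), 0.0) / DAYS_PER_YEAR
    return total
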