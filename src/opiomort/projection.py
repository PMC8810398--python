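"""Population-ageing counterfactual: apply modelled age-specific rates to an
external age-structure series.

Holding the age-specific cause-specific rates fixed and letting only the
population age distribution change over calendar time isolates how much of
a mortality trend ageing alone could produce.  The projection is a pure
weighted average — no refitting — so it is exactly linear in the rates and
invariant to the structure when the rates are flat in age.

The external structure (for the study population, the Unlinked Anonymous
Monitoring survey of people who inject drugs) is consumed as a year × age
weight table; because the survey microdata are not redistributable, a
synthetic generator is provided that matches stated under-40 anchor
proportions (89% in 2001, 52% in 2018) with a truncated-normal age profile
whose mean drifts over calendar time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ratemodel import StandardizedRateSeries

AGE_MIN, AGE_MAX = 18, 64  # inclusive single years of age

#: Under-40 proportion anchors for the default synthetic structure.
DEFAULT_ANCHORS = ((2001, 0.89), (2018, 0.52))

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "DEFAULT_ANCHORS",
    "AgeStructureSeries",
    "project",
    "percent_change",
    "synth_age_structure",
    "read_age_structure",
    "write_age_structure",
]


@dataclass
class AgeStructureSeries:
    """Calendar year → probability weights over single years of age."""

    table: pd.DataFrame  # columns: year, age, weight

    def __post_init__(self):
        t = self.table
        missing = {"year", "age", "weight"} - set(t.columns)
        if missing:
            raise ValueError(f"age structure missing columns: {sorted(missing)}")
        sums = t.groupby("year")["weight"].sum()
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)].index.tolist()
            raise ValueError(f"weights do not sum to 1 in years {bad}")
        if (t["age"] < AGE_MIN).any() or (t["age"] > AGE_MAX).any():
            raise ValueError(f"ages must lie in [{AGE_MIN}, {AGE_MAX}]")

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.table["year"].unique())

    def weights(self, year) -> pd.Series:
        sub = self.table[self.table["year"] == year]
        if len(sub) == 0:
            raise KeyError(f"year {year} not in structure")
        return sub.set_index("age")["weight"]

    def under_40(self, year) -> float:
        w = self.weights(year)
        return float(w[w.index < 40].sum())


def project(
    age_rates: StandardizedRateSeries, structure: AgeStructureSeries
) -> pd.Series:
    """Projected rate per 100 000 person-years for each structure year:
    ``rate(year) = Σ_a weight_a(year) × rate(a)``.

    Modelled rates are interpolated linearly between evaluated ages; any
    structure age outside the modelled support is an error.
    """
    if age_rates.axis != "age_years":
        raise ValueError("projection needs an age-specific rate series")
    tab = age_rates.table.sort_values("age_years")
    ages = tab["age_years"].to_numpy(dtype=float)
    rates = tab["rate"].to_numpy(dtype=float)
    out = {}
    for year in structure.years:
        w = structure.weights(year)
        a = w.index.to_numpy(dtype=float)
        if a.min() < ages.min() or a.max() > ages.max():
            raise ValueError(
                f"structure year {year} puts weight on ages outside the "
                f"modelled support [{ages.min():g}, {ages.max():g}]"
            )
        out[int(year)] = float(np.sum(w.to_numpy() * np.interp(a, ages, rates)))
    return pd.Series(out, name=age_rates.cause).sort_index()


def percent_change(series, year_from, year_to) -> float:
    """100 × (r_to − r_from) / r_from between two axis points of any
    rate mapping (a projection Series, or period rates)."""
    r0, r1 = series[year_from], series[year_to]
    if r0 == 0:
        raise ZeroDivisionError("rate at the origin point is zero")
    return 100.0 * (r1 - r0) / r0


def _truncnorm_weights(mean: float, sd: float) -> np.ndarray:
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    lo, hi = (AGE_MIN - mean) / sd, (AGE_MAX + 1 - mean) / sd
    dist = stats.truncnorm(lo, hi, loc=mean, scale=sd)
    w = dist.cdf(ages + 1) - dist.cdf(ages)
    return w / w.sum()


def _under40_mass(mean: float, sd: float) -> float:
    w = _truncnorm_weights(mean, sd)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    return float(w[ages < 40].sum())


def synth_age_structure(
    year_range=(2001, 2018),
    anchors=DEFAULT_ANCHORS,
    sd: float = 9.0,
    seed: int | None = None,
) -> AgeStructureSeries:
    """Synthetic drifting age structure matching under-40 anchors.

    For each year, the under-40 target is linearly interpolated between the
    anchor years (constant beyond them) and the mean of a truncated normal
    over ages 18–64 is solved so the under-40 mass hits the target.  The
    construction is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic generators.
    """
    anchors = sorted(anchors)
    for year, p in anchors:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"anchor for {year} outside [0, 1]: {p}")
    ay = np.array([a[0] for a in anchors], dtype=float)
    ap = np.array([a[1] for a in anchors], dtype=float)
    # the mean may drift outside the age support: truncation keeps the
    # weights on 18-64 while letting the under-40 mass approach 0 or 1
    m_lo, m_hi = AGE_MIN - 120.0, AGE_MAX + 120.0
    lo_mass = _under40_mass(m_lo, sd)
    hi_mass = _under40_mass(m_hi, sd)
    rows = []
    for year in range(year_range[0], year_range[1] + 1):
        target = float(np.interp(year, ay, ap))
        target_c = float(np.clip(target, hi_mass + 1e-12, lo_mass - 1e-12))
        mean = optimize.brentq(
            lambda m: _under40_mass(m, sd) - target_c, m_lo, m_hi, xtol=1e-10
        )
        w = _truncnorm_weights(mean, sd)
        for age, weight in zip(np.arange(AGE_MIN, AGE_MAX + 1), w):
            rows.append({"year": year, "age": int(age), "weight": float(weight)})
    return AgeStructureSeries(pd.DataFrame(rows))


def write_age_structure(structure: AgeStructureSeries, path) -> None:
    structure.table.to_csv(path, index=False)


def read_age_structure(path) -> AgeStructureSeries:
    return AgeStructureSeries(pd.read_csv(path, comment="#"))
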