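"""Descriptive outputs: baseline characteristics and cause-of-death shares."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .timeaxes import DAYS_PER_YEAR, period_label

__all__ = ["baseline_table", "proportion_of_deaths", "median_iqr"]


def median_iqr(values) -> tuple:
    """Median and interquartile range (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def proportion_of_deaths(observed_by_cause: pd.Series, total: int | None = None) -> pd.Series:
    """Each cause's share of deaths, in percent.

    ``total`` defaults to the sum of the counts; pass the all-cause count
    explicitly when the table is not exhaustive."""
    total = int(observed_by_cause.sum()) if total is None else int(total)
    if total <= 0:
        raise ValueError("no deaths to apportion")
    out = 100.0 * observed_by_cause / total
    out.name = "pct_of_deaths"
    return out


def _group_column(members, registry, exposed: bool) -> pd.Series:
    sub = members[members["exposed"] == exposed]
    reg = registry.set_index("person_id")
    entry = pd.to_datetime(sub["entry_date"])
    exit_ = pd.to_datetime(sub["exit_date"])
    birth = pd.to_datetime(reg["birth_date"].reindex(sub["person_id"]).to_numpy())
    sex = reg["sex"].reindex(sub["person_id"]).to_numpy()
    death = pd.to_datetime(reg["death_date"].reindex(sub["person_id"]).to_numpy())

    n = len(sub)
    col = {"n": f"{n}"}
    period = pd.Series(period_label(entry))
    for lab, cnt in period.value_counts().sort_index().items():
        col[f"entry period {lab}"] = f"{cnt} ({100 * cnt / n:.1f}%)"
    fu_m, fu_lo, fu_hi = median_iqr((exit_ - entry).dt.days / DAYS_PER_YEAR)
    col["follow-up years, median (IQR)"] = f"{fu_m:.1f} ({fu_lo:.1f}-{fu_hi:.1f})"
    age = (entry.to_numpy() - birth.to_numpy()).astype("timedelta64[D]").astype(float)
    a_m, a_lo, a_hi = median_iqr(age / DAYS_PER_YEAR)
    col["age at entry, median (IQR)"] = f"{a_m:.1f} ({a_lo:.1f}-{a_hi:.1f})"
    for s, label in (("F", "female"), ("M", "male")):
        cnt = int((sex == s).sum())
        col[f"sex {label}"] = f"{cnt} ({100 * cnt / n:.1f}%)"
    died = int((death.notna() & (death <= exit_.to_numpy())).sum())
    col["died during follow-up"] = f"{died} ({100 * died / n:.1f}%)"
    return pd.Series(col)


def baseline_table(members: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics at entry by exposure group (counts with
    percentages; medians with IQR).  Comparator slots are counted once per
    sampled slot, mirroring the matched design."""
    tab = pd.DataFrame(
        {
            "exposed": _group_column(members, registry, True),
            "comparison": _group_column(members, registry, False),
        }
    )
    tab.index.name = "characteristic"
    return tab.reset_index()
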