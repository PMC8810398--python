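"""Lexis expansion: split follow-up on calendar period, age, and time since
entry simultaneously, conserving person-time exactly in integer days.

Each member's follow-up ``[entry, exit)`` is cut at every calendar-period
start (2001–03 … 2016–18 bins), every birthday, and every third anniversary
of cohort entry falling strictly inside the interval.  Cells are half-open,
disjoint, contiguous and ordered; the death (if any) sits in the final cell.
Person-time is measured in years as days / 365.25, so the day totals are
conserved exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .timeaxes import DAYS_PER_YEAR, split_followup

__all__ = ["expand", "expand_cohort", "write_cells", "read_cells"]

_CELL_COLUMNS = [
    "member_id",
    "person_id",
    "exposed",
    "match_set_id",
    "sex",
    "period_bin",
    "age_years",
    "tse_band",
    "t0",
    "t1",
    "person_time",
    "event_cause",
]


def expand_cohort(
    members: pd.DataFrame,
    registry: pd.DataFrame,
    cause_col: str = "icd10",
) -> pd.DataFrame:
    """Expand every cohort member into Lexis cells.

    ``members`` carries person_id / exposed / entry_date / exit_date /
    match_set_id; sex, birth date and death information are joined from the
    registry.  A death is an event only when it falls on the member's exit
    date (a comparator censored before their death is event-free), and its
    cause is taken from ``registry[cause_col]``.
    """
    reg = registry.set_index("person_id")
    birth = pd.to_datetime(reg["birth_date"]).reindex(members["person_id"]).to_numpy()
    sex = reg["sex"].reindex(members["person_id"]).to_numpy()
    death = pd.to_datetime(reg["death_date"]).reindex(members["person_id"]).to_numpy()
    cause = reg[cause_col].reindex(members["person_id"]).to_numpy()

    entry = pd.to_datetime(members["entry_date"]).to_numpy()
    exit_ = pd.to_datetime(members["exit_date"]).to_numpy()
    cells = split_followup(entry, exit_, birth, tse_origin=entry)
    i = cells["idx"].to_numpy()

    # one member = one follow-up unit (a comparator drawn into two slots is
    # two members); member_id is the positional row in ``members``
    cells["member_id"] = i
    cells["person_id"] = members["person_id"].to_numpy()[i]
    cells["exposed"] = members["exposed"].to_numpy()[i]
    cells["match_set_id"] = members["match_set_id"].to_numpy()[i]
    cells["sex"] = sex[i]
    cells["person_time"] = cells["days"] / DAYS_PER_YEAR

    # event in the chronologically last cell, only if death caused the exit
    last = np.ones(len(i), dtype=bool)
    last[:-1] = i[:-1] != i[1:]
    is_event = last & pd.notna(death[i]) & (death[i] == exit_[i])
    cells["event_cause"] = pd.Series(
        np.where(is_event, cause[i], None), dtype=object
    )
    return cells[_CELL_COLUMNS].reset_index(drop=True)


def expand(member, birth_date, death_info=None, cause_col: str = "icd10") -> pd.DataFrame:
    """Expand a single member; scalar convenience over :func:`expand_cohort`.

    ``member`` needs person_id, exposed, entry_date, exit_date and (optional)
    match_set_id; ``death_info`` is ``(death_date, cause)`` or ``None``.
    """
    get = lambda k, d=None: (
        getattr(member, k) if hasattr(member, k) else member.get(k, d)
    )
    death_date, cause = (None, None) if death_info is None else death_info
    members = pd.DataFrame(
        {
            "person_id": [get("person_id")],
            "exposed": [bool(get("exposed", True))],
            "entry_date": [pd.Timestamp(get("entry_date"))],
            "exit_date": [pd.Timestamp(get("exit_date"))],
            "match_set_id": [get("match_set_id", 0)],
        }
    )
    registry = pd.DataFrame(
        {
            "person_id": [get("person_id")],
            "sex": [get("sex", "F")],
            "birth_date": [pd.Timestamp(birth_date)],
            "death_date": [pd.Timestamp(death_date) if death_date else pd.NaT],
            cause_col: [cause],
        }
    )
    return expand_cohort(members, registry, cause_col=cause_col)


def write_cells(cells: pd.DataFrame, path) -> None:
    out = cells.copy()
    for col in ("t0", "t1"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    cells = pd.read_csv(path, comment="#")
    for col in ("t0", "t1"):
        cells[col] = pd.to_datetime(cells[col])
    return cells
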