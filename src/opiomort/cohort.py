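"""Cohort construction: eligibility, washout, entry/exit dates, and 1:3
exposure-density matching.

Exposed members enter at the latest of the study start, twelve months after
registration (the washout), and their first exposure record, and must be
aged 18–64 at entry.  For each exposed member, three comparators of the same
sex and practice, within three years of age, alive, exposure-free at entry
and registered at least twelve months earlier, are sampled uniformly **with
replacement** and inherit the exposed member's entry date (exposure density
sampling).  A comparator who later acquires an exposure record is censored
as a comparator at that date.  An empty pool keeps the exposed member and
logs a warning: dropping exposed follow-up would bias rates.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeaxes import ADMIN_END, DAYS_PER_YEAR, STUDY_START, WASHOUT_DAYS

logger = logging.getLogger(__name__)

#: Comparators sampled per exposed member.
COMPARATORS_PER_EXPOSED = 3
#: Closed matching caliper on age at entry, in exact years.
AGE_CALIPER_YEARS = 3.0

__all__ = [
    "COMPARATORS_PER_EXPOSED",
    "AGE_CALIPER_YEARS",
    "IndividualRecord",
    "MatchedSet",
    "derive_entry_date",
    "derive_exit_date",
    "match_comparators",
    "build_cohort",
    "exact_age_years",
]


@dataclass(frozen=True)
class IndividualRecord:
    """One registry person (scalar counterpart of a registry row)."""

    person_id: object
    sex: str
    birth_date: dt.date
    practice_id: object
    registration_date: dt.date
    exposure_date: dt.date | None = None
    death_date: dt.date | None = None
    icd10: str | None = None


@dataclass
class MatchedSet:
    match_set_id: int
    exposed_person_id: object
    comparator_person_ids: list


def _get(record, name, default=None):
    if hasattr(record, name):
        value = getattr(record, name)
    else:
        value = record.get(name, default)
    if pd.isna(value):
        return None
    return value


def exact_age_years(birth_date, at) -> float:
    """Age in exact years (days / 365.25)."""
    return (pd.Timestamp(at) - pd.Timestamp(birth_date)).days / DAYS_PER_YEAR


def derive_entry_date(record, study_start=STUDY_START) -> pd.Timestamp:
    """Entry date of an exposed person: the latest of the study start,
    registration plus the 12-month washout, and the first exposure record."""
    exposure = _get(record, "exposure_date")
    if exposure is None:
        raise ValueError(
            "entry date requires an exposure record; comparators inherit "
            "entry from their matched exposed member"
        )
    registration = _get(record, "registration_date")
    return max(
        pd.Timestamp(study_start),
        pd.Timestamp(registration) + pd.Timedelta(days=WASHOUT_DAYS),
        pd.Timestamp(exposure),
    )


def derive_exit_date(record, admin_end=ADMIN_END) -> pd.Timestamp:
    """Exit date: the earlier of death and the administrative end."""
    death = _get(record, "death_date")
    end = pd.Timestamp(admin_end)
    if death is None:
        return end
    return min(pd.Timestamp(death), end)


class _MatchingIndex:
    """Registry pre-grouped by (sex, practice) for fast pool construction."""

    def __init__(self, registry: pd.DataFrame):
        def days(col):
            arr = pd.to_datetime(registry[col]).to_numpy().astype("datetime64[D]")
            out = arr.astype(np.float64)
            out[pd.isna(arr)] = np.nan  # NaT casts to a sentinel, not NaN
            return out

        self.person_id = registry["person_id"].to_numpy()
        self.birth = days("birth_date")
        self.registration = days("registration_date")
        self.exposure = days("exposure_date")  # NaN when never exposed
        self.death = days("death_date")
        self.groups = {
            key: np.asarray(idx)
            for key, idx in registry.groupby(
                ["sex", "practice_id"], sort=True
            ).indices.items()
        }

    def pool(self, sex, practice, entry_day: float, birth_day: float) -> np.ndarray:
        rows = self.groups.get((sex, practice))
        if rows is None:
            return np.empty(0, dtype=int)
        ok = (
            (self.registration[rows] + WASHOUT_DAYS <= entry_day)
            & ~(self.exposure[rows] <= entry_day)  # NaN-safe: never exposed passes
            & ~(self.death[rows] <= entry_day)
            & (
                np.abs(self.birth[rows] - birth_day)
                <= AGE_CALIPER_YEARS * DAYS_PER_YEAR
            )
        )
        return rows[ok]


def match_comparators(exposed, registry, rng, match_set_id=0) -> MatchedSet:
    """Sample three comparators for one exposed member.

    ``exposed`` needs ``person_id``, ``entry_date``, ``sex``, ``practice_id``
    and ``birth_date``; ``registry`` may be a DataFrame or a prebuilt
    :class:`_MatchingIndex`.  Sampling is uniform with replacement, so a pool
    of one yields the same comparator three times; an empty pool yields an
    empty comparator list with a logged warning.
    """
    index = registry if isinstance(registry, _MatchingIndex) else _MatchingIndex(registry)
    entry_day = float(
        np.datetime64(pd.Timestamp(_get(exposed, "entry_date")), "D").astype(np.int64)
    )
    birth_day = float(
        np.datetime64(pd.Timestamp(_get(exposed, "birth_date")), "D").astype(np.int64)
    )
    pid = _get(exposed, "person_id")
    pool = index.pool(_get(exposed, "sex"), _get(exposed, "practice_id"), entry_day, birth_day)
    pool = pool[index.person_id[pool] != pid]  # never one's own comparator
    if len(pool) == 0:
        logger.warning("empty matching pool for exposed person %r", pid)
        return MatchedSet(match_set_id, pid, [])
    draw = pool[rng.integers(0, len(pool), size=COMPARATORS_PER_EXPOSED)]
    return MatchedSet(match_set_id, pid, list(index.person_id[draw]))


def build_cohort(
    registry: pd.DataFrame,
    study_start=STUDY_START,
    admin_end=ADMIN_END,
    seed: int = 0,
):
    """Build the matched cohort from a registry table.

    Returns ``(members, sets)``.  ``members`` has one row per follow-up unit
    (an exposed member, or one comparator slot) with columns ``person_id``,
    ``exposed``, ``entry_date``, ``exit_date``, ``match_set_id``; ``sets``
    has one row per matched set with the comparator ids as a list column.
    The matching RNG is seeded here and independent of any other stream.
    """
    if registry["person_id"].duplicated().any():
        raise ValueError("registry contains duplicate person_ids")
    rng = np.random.default_rng(seed)
    index = _MatchingIndex(registry)
    study_start = pd.Timestamp(study_start)
    admin_end = pd.Timestamp(admin_end)

    reg = registry.set_index("person_id", drop=False)
    exposed_reg = reg[reg["exposure_date"].notna()].copy()
    entry = pd.concat(
        [
            pd.Series(study_start, index=exposed_reg.index),
            pd.to_datetime(exposed_reg["registration_date"])
            + pd.Timedelta(days=WASHOUT_DAYS),
            pd.to_datetime(exposed_reg["exposure_date"]),
        ],
        axis=1,
    ).max(axis=1)
    exit_ = pd.to_datetime(exposed_reg["death_date"]).fillna(admin_end).clip(upper=admin_end)
    age_entry = (entry - pd.to_datetime(exposed_reg["birth_date"])).dt.days / DAYS_PER_YEAR
    eligible = (age_entry >= 18.0) & (age_entry < 65.0) & (entry < exit_)
    exposed_reg = exposed_reg[eligible]
    entry, exit_ = entry[eligible], exit_[eligible]

    member_rows, set_rows = [], []
    for set_id, (pid, row) in enumerate(exposed_reg.iterrows()):
        e_entry, e_exit = entry[pid], exit_[pid]
        mset = match_comparators(
            {
                "person_id": pid,
                "entry_date": e_entry,
                "sex": row["sex"],
                "practice_id": row["practice_id"],
                "birth_date": row["birth_date"],
            },
            index,
            rng,
            match_set_id=set_id,
        )
        member_rows.append((pid, True, e_entry, e_exit, set_id))
        for cid in mset.comparator_person_ids:
            crow = reg.loc[cid]
            c_exit = derive_exit_date(crow, admin_end)
            cexp = crow["exposure_date"]
            if pd.notna(cexp):  # censor comparator at own exposure onset
                c_exit = min(c_exit, pd.Timestamp(cexp))
            member_rows.append((cid, False, e_entry, c_exit, set_id))
        set_rows.append((set_id, pid, mset.comparator_person_ids))

    members = pd.DataFrame(
        member_rows,
        columns=["person_id", "exposed", "entry_date", "exit_date", "match_set_id"],
    )
    sets = pd.DataFrame(
        set_rows, columns=["match_set_id", "exposed_person_id", "comparator_person_ids"]
    )
    n_empty = int((sets["comparator_person_ids"].str.len() == 0).sum())
    if n_empty:
        logger.warning("%d matched sets have an empty comparator pool", n_empty)
    return members, sets


def write_members(members: pd.DataFrame, path) -> None:
    out = members.copy()
    for col in ("entry_date", "exit_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_sets(sets: pd.DataFrame, path) -> None:
    out = sets.copy()
    out["comparator_person_ids"] = out["comparator_person_ids"].map(
        lambda ids: ";".join(str(i) for i in ids)
    )
    out.to_csv(path, index=False)


def read_members(path) -> pd.DataFrame:
    members = pd.read_csv(path, comment="#")
    for col in ("entry_date", "exit_date"):
        members[col] = pd.to_datetime(members[col])
    return members


def read_sets(path) -> pd.DataFrame:
    sets = pd.read_csv(path, comment="#")
    sets["comparator_person_ids"] = sets["comparator_person_ids"].map(
        lambda s: [] if pd.isna(s) or s == "" else [int(x) for x in str(s).split(";")]
    )
    return sets
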