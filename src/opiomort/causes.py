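"""ICD-10 underlying-cause grouping.

Deaths are classified three ways from the underlying-cause ICD-10 code:

* a **group** (infections, cancers, nervous system, circulatory, respiratory,
  digestive, external causes, drug poisoning);
* an optional **subgroup** (e.g. HIV, viral hepatitis, COPD, liver, suicide);
* a **mutually exclusive higher-level label** used for time and age trends:
  drug_poisoning, circulatory, copd, other_respiratory, respiratory_cancer,
  other_cancer, liver, external.

Drug poisoning is identified first, using the ONS underlying-cause
definition, and takes precedence over every disease group: an intentional
self-poisoning by narcotics is drug poisoning, never suicide or external.
Codes not matching any entry fall through to ``"other"`` and still count
towards all-cause mortality.

The codelist is data, not code: a delimited file with columns
``icd10_prefix, group, subgroup, exclusive_label`` that callers may replace
wholesale.  Classification is by longest matching prefix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

EXCLUSIVE_LABELS = (
    "drug_poisoning",
    "circulatory",
    "copd",
    "other_respiratory",
    "respiratory_cancer",
    "other_cancer",
    "liver",
    "external",
)

OTHER = "other"

#: Non-communicable diseases in this analysis: cancers plus circulatory,
#: respiratory and liver diseases (as exclusive trend labels).
NCD_CAUSES = (
    "circulatory",
    "copd",
    "other_respiratory",
    "respiratory_cancer",
    "other_cancer",
    "liver",
)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z.]*$")

__all__ = [
    "EXCLUSIVE_LABELS",
    "OTHER",
    "CauseCodelist",
    "load_default_codelist",
    "classify",
    "classify_series",
    "classify_cells",
    "validate_exclusive_partition",
]


@dataclass
class CauseCodelist:
    """Prefix-based ICD-10 codelist with the exclusive trend classification."""

    entries: pd.DataFrame
    exclusive_labels: tuple = EXCLUSIVE_LABELS
    _by_prefix: dict = field(init=False, repr=False)

    def __post_init__(self):
        required = {"icd10_prefix", "group", "subgroup", "exclusive_label"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"codelist missing columns: {sorted(missing)}")
        df = self.entries.fillna({"subgroup": "", "exclusive_label": ""})
        self.entries = df.reset_index(drop=True)
        # lookup table: first occurrence wins among disease groups, but
        # drug-poisoning prefixes shadow any disease-group entry outright
        lookup: dict = {}
        for r in self.entries.itertuples():
            triple = (r.group, r.subgroup or None, r.exclusive_label or OTHER)
            if r.group == "drug_poisoning":
                lookup[r.icd10_prefix] = triple
            else:
                lookup.setdefault(r.icd10_prefix, triple)
        self._by_prefix = lookup

    @property
    def max_prefix_len(self) -> int:
        return int(self.entries["icd10_prefix"].str.len().max())

    @classmethod
    def from_csv(cls, path) -> "CauseCodelist":
        return cls(pd.read_csv(path, dtype=str, comment="#"))


def load_default_codelist() -> CauseCodelist:
    """The codelist shipped with the package (ONS drug-poisoning definition
    plus conventional ICD-10 chapter/block prefixes for the disease groups)."""
    with resources.files("opiomort.data").joinpath("codelist.csv").open() as fh:
        return CauseCodelist(pd.read_csv(fh, dtype=str, comment="#"))


def classify(icd10: str, codelist: CauseCodelist) -> tuple:
    """Map one ICD-10 code to ``(group, subgroup, exclusive_label)``.

    Longest-prefix match; unmatched codes map to ``("other", None, "other")``.
    Malformed codes are rejected.
    """
    if not isinstance(icd10, str) or not _CODE_RE.match(icd10.replace(".", "")):
        raise ValueError(f"malformed ICD-10 code: {icd10!r}")
    code = icd10.replace(".", "")
    for ln in range(min(len(code), codelist.max_prefix_len), 0, -1):
        hit = codelist._by_prefix.get(code[:ln])
        if hit is not None:
            return hit
    return (OTHER, None, OTHER)


def classify_series(codes: pd.Series, codelist: CauseCodelist) -> pd.DataFrame:
    """Vectorised :func:`classify` over a Series (NaN passes through)."""
    uniq = codes.dropna().unique()
    mapping = {c: classify(c, codelist) for c in uniq}
    out = pd.DataFrame(index=codes.index)
    for i, col in enumerate(["cause_group", "cause_subgroup", "cause_exclusive"]):
        out[col] = codes.map(lambda c: mapping[c][i] if isinstance(c, str) else None)
    return out


def classify_cells(cells: pd.DataFrame, codelist: CauseCodelist) -> pd.DataFrame:
    """Attach cause columns to a Lexis cell table from its ``event_cause``
    ICD-10 codes (non-event cells keep missing values)."""
    labelled = cells.copy()
    labels = classify_series(cells["event_cause"], codelist)
    for col in labels.columns:
        labelled[col] = labels[col]
    return labelled


def validate_exclusive_partition(codelist: CauseCodelist) -> pd.DataFrame:
    """Report on the exclusive classification.

    Returns a DataFrame with one row per finding, ``kind`` in
    ``{"overlap", "gap"}``.  An overlap is a prefix that would receive two
    different exclusive labels; a gap is an exclusive label with no codes.
    This is a report, not an exception: an empty frame means a clean
    partition.
    """
    findings = []
    df = codelist.entries
    dup = df[df.duplicated("icd10_prefix", keep=False)]
    for prefix, grp in dup.groupby("icd10_prefix"):
        labels = set(grp["exclusive_label"].replace("", OTHER))
        # duplicates resolved by drug-poisoning precedence are intentional
        if len(labels) > 1 and "drug_poisoning" not in labels:
            findings.append(
                {"kind": "overlap", "detail": f"{prefix}: {sorted(labels)}"}
            )
    # nested prefixes mapping to different exclusive labels are intentional
    # refinements (e.g. J44 copd inside J other_respiratory), not overlaps:
    # longest-prefix match makes the assignment unique.
    present = set(df["exclusive_label"].replace("", OTHER)) - {OTHER}
    for label in codelist.exclusive_labels:
        if label not in present:
            findings.append({"kind": "gap", "detail": f"no codes map to {label}"})
    return pd.DataFrame(findings, columns=["kind", "detail"])
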