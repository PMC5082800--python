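"""Clinical code terminologies, hierarchy addressing, and exposure windows.

UK primary care records diagnoses with Read codes (hierarchical 5-byte
terminology: first character = chapter, first two = subchapter) while
hospital episodes carry ICD-10 codes (letter + digits, grouped in blocks
whose first two characters play the same subchapter role).  A linked
cohort therefore has two parallel hierarchies joined by a subchapter-level
mapping table.  This module owns those representations plus the two
exposure rules every downstream stage relies on:

* codes count toward a patient's comorbidity burden only when recorded
  strictly before a cutoff a fixed number of calendar months before the
  index date (terminal-illness coding in the final weeks would otherwise
  leak the outcome into the exposure), and
* a recent-hospitalisation indicator flags any hospital event in the year
  before index, again excluding the final pre-index months.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum

import pandas as pd

__all__ = [
    "Terminology",
    "Setting",
    "Code",
    "HierarchyAddress",
    "MappingTable",
    "ExposureWindow",
    "UNMAPPED",
    "MalformedCodeError",
    "normalize_code",
    "subchapter_of",
    "extract_exposures",
    "hospitalisation_flag",
    "read_events_csv",
    "read_mapping_csv",
    "read_code_list_csv",
    "months_before",
]

#: Sentinel returned by :meth:`MappingTable.map_group` for ICD subchapters
#: with no Read counterpart; such groups survive as ICD-only categories.
UNMAPPED = "unmapped"

_READ_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.]*$")
_ICD10_RE = re.compile(r"^[A-Z][0-9]{1,2}(\.[0-9A-Za-z]{1,2}|[0-9A-Za-z]{0,2})$")


class Terminology(str, Enum):
    READ = "READ"
    ICD10 = "ICD10"


class Setting(str, Enum):
    PRIMARY = "primary"
    HOSPITAL = "hospital"


class MalformedCodeError(ValueError):
    """A code string does not satisfy its terminology's pattern."""


def normalize_code(value: str, terminology: Terminology) -> str:
    """Canonical form used for prefix extraction and matching.

    ICD-10 codes are stored undotted in hospital data, so dots are
    stripped; Read codes keep their 5-byte form but trailing filler dots
    carry no meaning and are removed.
    """
    value = value.strip()
    if terminology == Terminology.ICD10:
        return value.replace(".", "").upper()
    return value.rstrip(".")


@dataclass(frozen=True)
class Code:
    """One terminology-native code string."""

    value: str
    terminology: Terminology

    def __post_init__(self) -> None:
        if not self.value or not self.value.strip():
            raise MalformedCodeError("empty code value")
        pattern = _READ_RE if self.terminology == Terminology.READ else _ICD10_RE
        if not pattern.match(self.value.strip()):
            raise MalformedCodeError(
                f"{self.value!r} is not a valid {self.terminology.value} code"
            )

    @property
    def normalized(self) -> str:
        return normalize_code(self.value, self.terminology)


@dataclass(frozen=True)
class HierarchyAddress:
    """Chapter / subchapter / code position of one code in its hierarchy."""

    chapter: str
    subchapter: str
    code: Code

    def __post_init__(self) -> None:
        if not self.subchapter.startswith(self.chapter):
            raise ValueError("chapter must prefix subchapter")
        if not self.code.normalized.startswith(self.subchapter):
            raise ValueError("subchapter must prefix the normalized code")


def subchapter_of(code: Code) -> HierarchyAddress:
    """Hierarchy address of a code: first character = chapter, first two
    characters of the dot-stripped code = subchapter."""
    norm = code.normalized
    if len(norm) < 2:
        raise MalformedCodeError(
            f"{code.value!r} has fewer than 2 characters after normalization"
        )
    return HierarchyAddress(chapter=norm[0], subchapter=norm[:2], code=code)


@dataclass
class MappingTable:
    """ICD-10 subchapter -> Read subchapter correspondence.

    Each ICD subchapter maps to at most one Read subchapter; several ICD
    subchapters may share a Read target, and unmapped subchapters are
    permitted (they stay ICD-only downstream).
    """

    entries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = dict(self.entries)

    def map_group(self, icd_subchapter: str) -> str:
        return self.entries.get(icd_subchapter, UNMAPPED)

    def __len__(self) -> int:
        return len(self.entries)


def months_before(anchor: date, months: int) -> date:
    """Calendar-month arithmetic: `anchor` minus `months`, clamping
    day-of-month overflow to the end of the target month (31 Mar - 1 month
    = 28/29 Feb)."""
    ts = pd.Timestamp(anchor) - pd.DateOffset(months=months)
    return ts.date()


@dataclass(frozen=True)
class ExposureWindow:
    """Pre-index window from which diagnosis codes count as exposures.

    Events on/after ``cutoff = index_date - exclusion_months`` are
    discarded so that coding of the final stage of life does not enter the
    comorbidity score.
    """

    index_date: date
    exclusion_months: int = 2
    lookback_start: date | None = None

    def __post_init__(self) -> None:
        if self.exclusion_months < 0:
            raise ValueError("exclusion_months must be >= 0")

    @property
    def cutoff(self) -> date:
        return months_before(self.index_date, self.exclusion_months)


_EVENT_COLUMNS = ["patient_id", "code", "terminology", "event_date", "setting"]


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    out = events.copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.date
    bad_setting = ~out["setting"].isin([s.value for s in Setting])
    if bad_setting.any():
        raise ValueError("unknown setting values in events table")
    hosp = out["setting"] == Setting.HOSPITAL.value
    if (out.loc[hosp, "terminology"] != Terminology.ICD10.value).any():
        raise ValueError("hospital events must carry ICD10 codes")
    if (out.loc[~hosp, "terminology"] != Terminology.READ.value).any():
        raise ValueError("primary care events must carry READ codes")
    return out


def extract_exposures(events: pd.DataFrame, window: ExposureWindow) -> pd.DataFrame:
    """Window-filter coded events into per-patient exposure sets.

    Keeps events dated strictly before the window cutoff (and on/after
    ``lookback_start`` when given) and collapses duplicates to one row per
    (patient, code, setting); recurrence counts play no role in the score.

    Returns a DataFrame with columns patient_id, code, terminology,
    subchapter, chapter, setting.
    """
    if len(events) == 0:
        return pd.DataFrame(
            columns=["patient_id", "code", "terminology", "subchapter", "chapter", "setting"]
        )
    ev = _validate_events(events)
    keep = ev["event_date"] < window.cutoff
    if window.lookback_start is not None:
        keep &= ev["event_date"] >= window.lookback_start
    ev = ev.loc[keep, ["patient_id", "code", "terminology", "setting"]]
    ev = ev.drop_duplicates(subset=["patient_id", "code", "setting"])
    # malformed codes are rejected here, at load time, so downstream
    # subchapter extraction cannot fail
    norm = [
        normalize_code(v, Terminology(t))
        for v, t in zip(ev["code"], ev["terminology"])
    ]
    if any(len(n) < 2 for n in norm):
        offenders = sorted({v for v, n in zip(ev["code"], norm) if len(n) < 2})
        raise MalformedCodeError(f"codes too short after normalization: {offenders}")
    ev = ev.assign(
        subchapter=[n[:2] for n in norm],
        chapter=[n[0] for n in norm],
    )
    return ev.reset_index(drop=True)[
        ["patient_id", "code", "terminology", "subchapter", "chapter", "setting"]
    ]


def hospitalisation_flag(
    events: pd.DataFrame,
    index_date: date,
    patient_ids=None,
    exclusion_months: int = 2,
) -> pd.Series:
    """Recent-hospitalisation indicator.

    True for patients with any hospital event in the year before the index
    date, excluding the final ``exclusion_months`` months: the window is
    ``[index - 12 months, index - exclusion_months)``.  When
    ``patient_ids`` is given the result is reindexed over it with False
    for patients without qualifying events.
    """
    lo = months_before(index_date, 12)
    hi = months_before(index_date, exclusion_months)
    if len(events):
        ev = _validate_events(events)
        hosp = ev[
            (ev["setting"] == Setting.HOSPITAL.value)
            & (ev["event_date"] >= lo)
            & (ev["event_date"] < hi)
        ]
        flagged = pd.Series(True, index=pd.Index(hosp["patient_id"].unique()))
    else:
        flagged = pd.Series(dtype=bool)
    if patient_ids is not None:
        return flagged.reindex(patient_ids, fill_value=False).astype(bool)
    return flagged


def read_events_csv(path) -> pd.DataFrame:
    """Load an events table (patient_id,code,terminology,event_date,setting)."""
    return _validate_events(pd.read_csv(path))


def read_mapping_csv(path) -> MappingTable:
    """Load an ICD->Read subchapter mapping (icd_subchapter,read_subchapter)."""
    df = pd.read_csv(path, dtype=str)
    if df["icd_subchapter"].duplicated().any():
        dupes = sorted(df.loc[df["icd_subchapter"].duplicated(), "icd_subchapter"])
        raise ValueError(f"ICD subchapters mapped more than once: {dupes}")
    return MappingTable(dict(zip(df["icd_subchapter"], df["read_subchapter"])))


def read_code_list_csv(path, terminology: Terminology) -> pd.DataFrame:
    """Load a category code list in the two-column layout
    (category_label,code); tolerant of quoted fields.

    Returns a DataFrame with columns category_label, code (normalized).
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"category_label", "code"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns category_label,code")
    df["code"] = [normalize_code(v, terminology) for v in df["code"]]
    return df[["category_label", "code"]]
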