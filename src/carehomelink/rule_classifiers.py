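"""Rule-based care-home classifiers: household size/age and coded events.

Two of the three residency-identification methods live here:

* the household decision rule — a patient aged >= 65 living in a (valid)
  household with at least three *other* members aged >= 65 is a potential
  care-home resident;
* the codelist classifier — a patient with at least one clinical event whose
  SNOMED code is in a care-home codelist, dated inside a time window
  ("ever" up to the index date, the past year, or an explicit interval),
  is a potential care-home resident.

The shipped PRIMIS codelist carries six SNOMED codes; its incentivised
subset is the two codes general practices are paid to maintain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._common import age_at, as_timestamp, year_before
from .errors import CodelistError

logger = logging.getLogger(__name__)

INVALID_HOUSEHOLD_ID = 0

__all__ = [
    "Codelist",
    "CodelistEntry",
    "load_codelist",
    "builtin_codelist",
    "classify_household_rule",
    "classify_coded_events",
    "household_data_quality",
    "INVALID_HOUSEHOLD_ID",
]


# --------------------------------------------------------------------------
# Codelists
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CodelistEntry:
    code: str
    term: str
    incentivised: bool


@dataclass(frozen=True)
class Codelist:
    """An immutable set of clinical codes with an optional incentivised subset."""

    name: str
    entries: tuple[CodelistEntry, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise CodelistError(f"codelist {self.name!r} has duplicate codes: {dupes}")

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(e.code for e in self.entries)

    @property
    def incentivised(self) -> "Codelist":
        return Codelist(
            name=f"{self.name}_incentivised",
            entries=tuple(e for e in self.entries if e.incentivised),
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code) -> bool:
        return str(code) in self.codes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [e.code for e in self.entries],
                "term": [e.term for e in self.entries],
                "incentivised": ["Y" if e.incentivised else "N" for e in self.entries],
            }
        )


_TRUTHY = {"y", "yes", "true", "1"}


def _entries_from_frame(frame: pd.DataFrame, source: str) -> tuple[CodelistEntry, ...]:
    for column in ("code", "term"):
        if column not in frame.columns:
            raise CodelistError(f"codelist {source} is missing column {column!r}")
    if frame.empty:
        raise CodelistError(f"codelist {source} is empty")
    incentivised = (
        frame["incentivised"].astype(str).str.strip().str.lower().isin(_TRUTHY)
        if "incentivised" in frame.columns
        else pd.Series(False, index=frame.index)
    )
    return tuple(
        CodelistEntry(code=str(code).strip(), term=str(term).strip(), incentivised=bool(flag))
        for code, term, flag in zip(frame["code"], frame["term"], incentivised)
    )


def load_codelist(path, name: str | None = None) -> Codelist:
    """Load a codelist from a CSV with columns ``code,term[,incentivised]``."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise CodelistError(f"codelist {path} is empty") from None
    return Codelist(name=name or path.stem, entries=_entries_from_frame(frame, str(path)))


def builtin_codelist(name: str = "primis") -> Codelist:
    """Return a shipped codelist: ``primis`` (six codes) or ``incentivised`` (two)."""
    key = name.strip().lower().replace("-", "_")
    ref = resources.files("carehomelink.codelists").joinpath("primis_care_home.csv")
    with resources.as_file(ref) as path:
        primis = load_codelist(path, name="primis")
    if key == "primis":
        return primis
    if key == "incentivised":
        return primis.incentivised
    raise CodelistError(f"unknown builtin codelist {name!r}; choose 'primis' or 'incentivised'")


# --------------------------------------------------------------------------
# Household size/age rule
# --------------------------------------------------------------------------

def classify_household_rule(
    patients: pd.DataFrame,
    households: pd.DataFrame | None = None,
    *,
    index_date,
    min_age: int = 65,
    min_other_members: int = 3,
) -> pd.Series:
    """Flag patients in large elderly households as potential care-home residents.

    A patient is flagged when they are aged ``min_age`` or older and share a
    household (id != 0) with at least ``min_other_members`` other patients
    who are also aged ``min_age`` or older. Household membership is counted
    from the resolved patient rows, not from any stored household-size field;
    when a ``households`` table is supplied, discrepancies between the two
    are logged.

    Returns a boolean Series indexed by patient_id.
    """
    ages = age_at(patients, index_date)
    household_ids = patients["household_id"].fillna(INVALID_HOUSEHOLD_ID).astype("int64")
    valid = household_ids != INVALID_HOUSEHOLD_ID
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("household rule: %d patients with invalid household id 0 excluded", n_invalid)

    qualifying = (ages >= min_age) & valid
    elder_counts = household_ids[qualifying].value_counts()
    members_needed = min_other_members + 1  # the patient plus the required others
    big_households = set(elder_counts[elder_counts >= members_needed].index)

    flags = qualifying & household_ids.isin(big_households)
    flags.index = patients["patient_id"].values
    flags.name = "household_rule"

    if households is not None and not households.empty:
        member_counts = household_ids[valid].value_counts()
        stored = households.set_index("household_id")["household_size"]
        common = stored.index.intersection(member_counts.index)
        mismatched = (stored.loc[common] < member_counts.loc[common]).sum()
        if mismatched:
            logger.warning(
                "household rule: %d households report a stored size below their member count",
                int(mismatched),
            )
    return flags


def household_data_quality(patients: pd.DataFrame) -> dict:
    """Counts the rule's data-quality exclusions (invalid household ids)."""
    household_ids = patients["household_id"].fillna(INVALID_HOUSEHOLD_ID).astype("int64")
    return {
        "n_patients": int(len(patients)),
        "n_invalid_household_id": int((household_ids == INVALID_HOUSEHOLD_ID).sum()),
    }


# --------------------------------------------------------------------------
# Coded-event classifier
# --------------------------------------------------------------------------

def _resolve_window(window, index_date) -> tuple[pd.Timestamp | None, pd.Timestamp]:
    index_ts = as_timestamp(index_date)
    if isinstance(window, str):
        key = window.strip().lower().replace("-", "_")
        if key == "ever":
            return None, index_ts
        if key == "past_year":
            return year_before(index_ts), index_ts
        raise ValueError(f"unknown window {window!r}; use 'ever', 'past_year' or (start, end)")
    start, end = window
    return (None if start is None else as_timestamp(start)), as_timestamp(end)


def classify_coded_events(
    events: pd.DataFrame,
    codelist: Codelist,
    *,
    index_date,
    window: str | tuple = "ever",
    patient_ids: Iterable | Sequence | None = None,
) -> pd.Series:
    """Flag patients with a codelist event dated inside the window.

    Window semantics: ``"ever"`` means on or before the index date;
    ``"past_year"`` means the closed interval [index_date - 1 year,
    index_date] (29 Feb anniversaries map to 28 Feb); an explicit
    ``(start, end)`` pair is treated as a closed interval, with ``start=None``
    meaning unbounded below. Rows whose event date fails to parse are
    rejected and counted in the log.

    Returns a boolean Series indexed by patient_id, over ``patient_ids``
    when given, otherwise over the patients present in ``events``.
    """
    if len(codelist) == 0:
        raise CodelistError("cannot classify with an empty codelist")
    start, end = _resolve_window(window, index_date)

    dates = pd.to_datetime(events["event_date"], errors="coerce") if len(events) else pd.Series(dtype="datetime64[ns]")
    n_bad = int(dates.isna().sum())
    if n_bad:
        logger.warning("coded events: %d rows rejected for unparseable event_date", n_bad)

    if len(events):
        in_list = events["code"].astype(str).str.strip().isin(codelist.codes)
        in_window = dates.notna() & (dates <= end)
        if start is not None:
            in_window &= dates >= start
        flagged_ids = pd.unique(events.loc[in_list & in_window, "patient_id"])
    else:
        flagged_ids = []

    if patient_ids is None:
        index = pd.Index(sorted(pd.unique(events["patient_id"])) if len(events) else [], name="patient_id")
    else:
        index = pd.Index(patient_ids, name="patient_id")
    flags = pd.Series(index.isin(flagged_ids), index=index, name="coded_events")
    return flags
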