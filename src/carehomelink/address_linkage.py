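"""Complex address linkage of GP-registered addresses to a CQC-style care-home register.

The algorithm identifies potential care-home residents in four stages:

1. **Postcode superset match** — every patient address whose postcode equals a
   register postcode is a candidate. This deliberately over-selects: private
   homes share postcodes with care homes.
2. **Refinement criteria**, any one of which confirms a candidate:

   a. *house-name match* — the register building name, after simple
      normalisation (uppercasing, punctuation stripping, a fixed abbreviation
      table, a fixed stop-token set), equals the normalised house-name text of
      the address (other free-text fields are tried when the house name fails);
   b. *house-number match* — when at least ``number_threshold`` (default 10)
      name-matched address records carry the same house number, that number is
      taken to identify the home within its postcode, and any address in the
      postcode with that number matches;
   c. *household-size match* — when at least ``size_threshold`` (default 10)
      patients aged 65+ are registered at the identical address in the
      postcode of an old-age home, those patients match. This misses smaller
      homes by design.

3. **Date filters** — only register entries active at the index date are
   matched against addresses valid at the index date.
4. **Nursing categorisation** — confirmed matches are labelled
   ``care_home_nursing`` / ``care_home_no_nursing`` from the register's
   nursing-requirement flags, ``care_home_misc`` otherwise; everyone else is
   ``private_home``.

By default statuses are only assigned to patients aged 65 or older: the
register covers old-age homes only, and younger postcode/name matches are
more often live-in carers or family members than residents.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._common import age_at, as_timestamp, clean_number_token
from .errors import DataIntegrityError

logger = logging.getLogger(__name__)

CARE_HOME_NURSING = "care_home_nursing"
CARE_HOME_NO_NURSING = "care_home_no_nursing"
CARE_HOME_MISC = "care_home_misc"
PRIVATE_HOME = "private_home"
STATUSES = (CARE_HOME_NURSING, CARE_HOME_NO_NURSING, CARE_HOME_MISC, PRIVATE_HOME)

NAME_MATCH = "name_match"
NUMBER_MATCH = "number_match"
SIZE_MATCH = "size_match"

# Canonical form is the expanded word; both directions normalise identically.
ABBREVIATIONS: Mapping[str, str] = {
    "ST": "SAINT",
    "HSE": "HOUSE",
    "RD": "ROAD",
}

STOP_TOKENS = frozenset({"THE", "CARE", "HOME", "NURSING", "RESIDENTIAL"})

_APOSTROPHES = re.compile(r"[’']")
_NON_ALNUM = re.compile(r"[^A-Z0-9]+")

__all__ = [
    "normalize_building_name",
    "normalized_name_key",
    "match_postcode",
    "match_house_name",
    "derive_house_numbers",
    "match_house_number",
    "match_household_size",
    "classify_address_linkage",
    "active_register",
    "active_addresses",
    "STATUSES",
    "CARE_HOME_NURSING",
    "CARE_HOME_NO_NURSING",
    "CARE_HOME_MISC",
    "PRIVATE_HOME",
]


# --------------------------------------------------------------------------
# Building-name normalisation (criterion a's "simple NLP")
# --------------------------------------------------------------------------

def normalize_building_name(
    name,
    *,
    abbreviations: Mapping[str, str] = ABBREVIATIONS,
    stop_tokens: frozenset[str] = STOP_TOKENS,
) -> tuple[str, ...]:
    """Normalise a building name to an ordered token tuple.

    Uppercases, deletes apostrophes (``Mary's`` -> ``MARYS``), replaces other
    punctuation with spaces, collapses whitespace, canonicalises the fixed
    abbreviation table to its expanded form, and drops the fixed stop tokens.
    Deterministic; empty or missing input gives an empty tuple.
    """
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return ()
    text = _APOSTROPHES.sub("", str(name).upper())
    text = _NON_ALNUM.sub(" ", text)
    tokens = []
    for token in text.split():
        token = abbreviations.get(token, token)
        if token not in stop_tokens:
            tokens.append(token)
    return tuple(tokens)


def normalized_name_key(name) -> str:
    """The normalised token sequence as a single space-joined key ('' if empty)."""
    return " ".join(normalize_building_name(name))


# --------------------------------------------------------------------------
# Date filters (closed intervals; missing end date = still active/current)
# --------------------------------------------------------------------------

def _interval_active(frame: pd.DataFrame, start_col: str, end_col: str, index_date) -> pd.Series:
    ts = as_timestamp(index_date)
    start = pd.to_datetime(frame[start_col], errors="coerce") if start_col in frame else None
    end = pd.to_datetime(frame[end_col], errors="coerce") if end_col in frame else None
    active = pd.Series(True, index=frame.index)
    if start is not None:
        active &= start.isna() | (start <= ts)
    if end is not None:
        active &= end.isna() | (end >= ts)
    return active


def active_register(register: pd.DataFrame, index_date) -> pd.DataFrame:
    """Register entries whose registration interval covers the index date."""
    return register[_interval_active(register, "registered_from", "registered_to", index_date)]


def active_addresses(addresses: pd.DataFrame, index_date) -> pd.DataFrame:
    """Address records whose validity interval covers the index date."""
    return addresses[_interval_active(addresses, "valid_from", "valid_to", index_date)]


# --------------------------------------------------------------------------
# Stage 1: postcode superset match
# --------------------------------------------------------------------------

def match_postcode(addresses: pd.DataFrame, register: pd.DataFrame) -> pd.DataFrame:
    """All (address_id, location_id) pairs sharing an exact postcode.

    Explicitly a superset: private homes sharing a care-home postcode are
    included and must be excluded later unless a refinement criterion fires.
    """
    addr = addresses.loc[addresses["postcode"].astype(str).str.strip() != "", ["address_id", "postcode"]]
    reg = register[["location_id", "postcode"]]
    pairs = addr.merge(reg, on="postcode")[["address_id", "location_id"]]
    return pairs.drop_duplicates().sort_values(["address_id", "location_id"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# Criterion a: house-name match
# --------------------------------------------------------------------------

def _address_name_keys(addresses: pd.DataFrame) -> pd.DataFrame:
    keys = addresses[["address_id"]].copy()
    keys["house_name_key"] = addresses.get("house_name", pd.Series(index=addresses.index, dtype=object)).map(
        normalized_name_key
    )
    other = addresses.get("other_text", pd.Series(index=addresses.index, dtype=object))
    keys["other_text_key"] = other.map(normalized_name_key)
    return keys


def match_house_name(
    candidates: pd.DataFrame, addresses: pd.DataFrame, register: pd.DataFrame
) -> pd.DataFrame:
    """Candidate pairs whose normalised names agree: evidence ``name_match``.

    The register building name is compared with the address house-name field;
    other free-text address fields are tried when the house name fails.
    """
    reg = register[["location_id", "building_name"]].copy()
    reg["name_key"] = reg["building_name"].map(normalized_name_key)
    reg = reg[reg["name_key"] != ""]
    merged = candidates.merge(_address_name_keys(addresses), on="address_id").merge(
        reg[["location_id", "name_key"]], on="location_id"
    )
    hit = (merged["house_name_key"] == merged["name_key"]) | (
        merged["other_text_key"] == merged["name_key"]
    )
    return (
        merged.loc[hit, ["address_id", "location_id"]]
        .drop_duplicates()
        .sort_values(["address_id", "location_id"])
        .reset_index(drop=True)
    )


# --------------------------------------------------------------------------
# Criterion b: derived house numbers
# --------------------------------------------------------------------------

def derive_house_numbers(
    addresses: pd.DataFrame,
    register: pd.DataFrame,
    *,
    threshold: int = 10,
) -> pd.DataFrame:
    """Derive the house number identifying each care home within its postcode.

    For each register entry, among address records in its postcode that match
    its building name and carry a house number, any number shared by at least
    ``threshold`` distinct address records is taken to identify the home.
    Returns a frame with columns location_id, postcode, house_number.
    """
    empty = pd.DataFrame(columns=["location_id", "postcode", "house_number"])
    if addresses.empty or register.empty:
        return empty
    candidates = match_postcode(addresses, register)
    named = match_house_name(candidates, addresses, register)
    if named.empty:
        return empty
    numbers = addresses[["address_id"]].copy()
    numbers["house_number"] = addresses.get("house_number").map(clean_number_token)
    named = named.merge(numbers, on="address_id").dropna(subset=["house_number"])
    if named.empty:
        return empty
    counts = (
        named.groupby(["location_id", "house_number"])["address_id"].nunique().reset_index(name="n")
    )
    derived = counts[counts["n"] >= threshold][["location_id", "house_number"]]
    out = derived.merge(register[["location_id", "postcode"]], on="location_id")
    return out[["location_id", "postcode", "house_number"]].sort_values(
        ["location_id", "house_number"]
    ).reset_index(drop=True)


def match_house_number(
    candidates: pd.DataFrame,
    addresses: pd.DataFrame,
    derived_numbers: pd.DataFrame,
) -> pd.DataFrame:
    """Candidate pairs whose house number equals a derived care-home number.

    The candidate set already guarantees the address sits in the care home's
    postcode; the derived number identifies the home within that postcode.
    Evidence ``number_match``.
    """
    if candidates.empty or derived_numbers.empty:
        return pd.DataFrame(columns=["address_id", "location_id"])
    numbers = addresses[["address_id"]].copy()
    numbers["house_number"] = addresses.get("house_number").map(clean_number_token)
    numbers = numbers.dropna(subset=["house_number"])
    merged = candidates.merge(numbers, on="address_id").merge(
        derived_numbers[["location_id", "house_number"]], on=["location_id", "house_number"]
    )
    return (
        merged[["address_id", "location_id"]]
        .drop_duplicates()
        .sort_values(["address_id", "location_id"])
        .reset_index(drop=True)
    )


# --------------------------------------------------------------------------
# Criterion c: household-size match
# --------------------------------------------------------------------------

def match_household_size(
    candidates: pd.DataFrame,
    patients: pd.DataFrame,
    addresses: pd.DataFrame,
    register: pd.DataFrame,
    index_date,
    *,
    threshold: int = 10,
    min_age: int = 65,
) -> pd.DataFrame:
    """Candidate pairs at addresses housing ``threshold``+ patients aged 65+.

    Only postcodes of old-age homes qualify, and the count is over patients
    registered at the identical address record. Evidence ``size_match``
    (applies, per patient, only to those aged >= ``min_age``).
    """
    if candidates.empty:
        return pd.DataFrame(columns=["address_id", "location_id"])
    old_age = register.loc[register["old_age_home"].astype(bool), "location_id"]
    cand = candidates[candidates["location_id"].isin(set(old_age))]
    if cand.empty:
        return pd.DataFrame(columns=["address_id", "location_id"])
    ages = age_at(patients, index_date)
    elder_counts = patients.loc[ages >= min_age, "address_id"].value_counts()
    big_addresses = set(elder_counts[elder_counts >= threshold].index)
    return (
        cand[cand["address_id"].isin(big_addresses)]
        .drop_duplicates()
        .sort_values(["address_id", "location_id"])
        .reset_index(drop=True)
    )


# --------------------------------------------------------------------------
# Orchestration: classify every patient
# --------------------------------------------------------------------------

def _check_foreign_keys(patients: pd.DataFrame, addresses: pd.DataFrame) -> None:
    known = set(addresses["address_id"])
    dangling = sorted(set(patients["address_id"].dropna()) - known)
    if dangling:
        raise DataIntegrityError(
            f"patients reference {len(dangling)} unknown address ids, e.g. {dangling[:10]}"
        )


def _status_from_entry(entry: pd.Series) -> str:
    requires = str(entry.get("requires_nursing", "")).strip().upper()
    does_not = str(entry.get("does_not_require_nursing", "")).strip().upper()
    if does_not == "Y" and requires == "N":
        return CARE_HOME_NO_NURSING
    if does_not == "N" and requires == "Y":
        return CARE_HOME_NURSING
    if requires == "Y" and does_not == "Y":
        logger.warning(
            "register entry %s has contradictory nursing flags (both Y); categorised %s",
            entry.name,
            CARE_HOME_MISC,
        )
    return CARE_HOME_MISC


def classify_address_linkage(
    patients: pd.DataFrame,
    addresses: pd.DataFrame,
    register: pd.DataFrame,
    *,
    index_date,
    size_threshold: int = 10,
    number_threshold: int = 10,
    min_age: int = 65,
    restrict_to_min_age: bool = True,
) -> pd.DataFrame:
    """Classify every patient's care-home status at ``index_date``.

    A patient is a potential care-home resident iff their current address has
    a postcode match to a register entry active at the index date AND at least
    one refinement criterion (name, number, size) fires. Confirmed matches are
    categorised from the entry's nursing flags; all other patients are
    ``private_home``. When several active homes match one address, the entry
    with a name match is preferred, then the lexicographically smallest
    location_id (the care-home status itself is unaffected; the tie is logged).

    Returns one row per patient: patient_id, status, evidence (comma-joined,
    empty iff private_home), matched_location_id.
    """
    _check_foreign_keys(patients, addresses)

    reg = active_register(register, index_date)
    addr = active_addresses(addresses, index_date)

    candidates = match_postcode(addr, reg)
    named = match_house_name(candidates, addr, reg)
    derived = derive_house_numbers(addr, reg, threshold=number_threshold)
    numbered = match_house_number(candidates, addr, derived)
    sized = match_household_size(
        candidates, patients, addr, reg, index_date, threshold=size_threshold, min_age=min_age
    )

    evidence_frames = [
        named.assign(evidence=NAME_MATCH),
        numbered.assign(evidence=NUMBER_MATCH),
        sized.assign(evidence=SIZE_MATCH),
    ]
    pairs = pd.concat(evidence_frames, ignore_index=True)

    ages = age_at(patients, index_date)
    result = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].values,
            "status": PRIVATE_HOME,
            "evidence": "",
            "matched_location_id": None,
        }
    )

    if pairs.empty:
        return result

    # Evidence per (address, location); size evidence is age-gated per patient.
    pair_evidence = (
        pairs.groupby(["address_id", "location_id"])["evidence"]
        .agg(lambda values: frozenset(values))
        .reset_index()
    )
    patient_addr = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].values,
            "address_id": patients["address_id"].values,
            "age": ages.values,
        }
    )
    matches = patient_addr.merge(pair_evidence, on="address_id")
    if matches.empty:
        return result

    def _gate(row) -> frozenset:
        ev = row["evidence"]
        if row["age"] < min_age and SIZE_MATCH in ev:
            ev = ev - {SIZE_MATCH}
        return ev

    matches["evidence"] = matches.apply(_gate, axis=1)
    matches = matches[matches["evidence"].map(len) > 0]

    if restrict_to_min_age:
        under_age = matches["age"] < min_age
        n_young = matches.loc[under_age, "patient_id"].nunique()
        if n_young:
            logger.info(
                "address linkage: %d matched patients aged under %d classified %s "
                "(possible live-in carers or family members)",
                n_young,
                min_age,
                PRIVATE_HOME,
            )
        matches = matches[~under_age]
    if matches.empty:
        return result

    reg_indexed = reg.set_index("location_id")

    matches = matches.assign(
        has_name=matches["evidence"].map(lambda ev: NAME_MATCH in ev)
    ).sort_values(["patient_id", "has_name", "location_id"], ascending=[True, False, True])

    chosen_rows = []
    for patient_id, group in matches.groupby("patient_id", sort=False):
        if group["location_id"].nunique() > 1:
            logger.info(
                "address linkage: patient %s matches %d active homes; using %s",
                patient_id,
                group["location_id"].nunique(),
                group.iloc[0]["location_id"],
            )
        evidence = frozenset().union(*group["evidence"])
        chosen = group.iloc[0]["location_id"]
        status = _status_from_entry(reg_indexed.loc[chosen])
        chosen_rows.append((patient_id, status, ",".join(sorted(evidence)), chosen))

    flagged = pd.DataFrame(
        chosen_rows, columns=["patient_id", "status", "evidence", "matched_location_id"]
    )
    result = result.set_index("patient_id")
    flagged = flagged.set_index("patient_id")
    result.loc[flagged.index, ["status", "evidence", "matched_location_id"]] = flagged[
        ["status", "evidence", "matched_location_id"]
    ]
    return result.reset_index()


def flags_from_classification(classification: pd.DataFrame) -> pd.Series:
    """Boolean residency flag per patient from a classification frame."""
    flags = classification["status"].ne(PRIVATE_HOME)
    flags.index = classification["patient_id"].values
    flags.name = "address_linkage"
    return flags
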