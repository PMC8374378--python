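"""Synthetic population, address universe, care-home register and coded events.

Real pseudonymised GP records cannot leave their secure environment, so this
module plants a fully known ground truth and emulates the error structure
that makes care-home identification hard in practice:

* **stale addresses** — a fraction of true residents keep their old private
  address in the GP record (address linkage and the household rule both miss
  them);
* **house-name variants** — registered address text is a corrupted variant
  of the register name (abbreviations, punctuation, suffix drops, token
  reorderings, case changes);
* **shared postcodes** — some private dwellings share a care-home postcode,
  so postcode matching alone over-selects;
* **under-coding** — only a fraction of true residents ever receive a
  care-home SNOMED code, and a small fraction of non-residents are falsely
  coded;
* **temporary stays** — labelled in the ground truth but left at the
  resident's private address, since none of the identification methods is
  expected to capture them;
* **demographics correlated with residency** — female sex, age over 80,
  white ethnicity, dementia and stroke are enriched among residents via
  configurable odds multipliers.

Every output is a deterministic function of the configuration seed.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._common import as_timestamp, random_dob_for_age
from .errors import ConfigurationError, GenerationError
from .rule_classifiers import Codelist, builtin_codelist

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "SimulatedData",
    "generate_register",
    "generate_population",
    "generate_coded_events",
    "corrupt_name",
    "simulate",
    "write_fixture_set",
    "score_against_truth",
    "FIXTURE_FILES",
]

# Base rates among the 65+ general population, used together with the
# configured odds multipliers to draw resident demographics.
BASE_RATES_65PLUS = {
    "female": 0.538,
    "over_80": 0.272,
    "white": 0.942,
    "dementia": 0.0483,
    "stroke": 0.0668,
}
_BASE_RATES_UNDER65 = {"female": 0.51, "white": 0.92, "dementia": 0.002, "stroke": 0.008}

# Default demographic enrichment of residents over the 65+ base rates,
# expressed as odds ratios (residents are older, more often female, and far
# more often have dementia).
DEFAULT_DEMOGRAPHICS_ODDS = {
    "female": 2.0,
    "over_80": 10.1,
    "white": 2.9,
    "dementia": 28.7,
    "stroke": 3.9,
}

DEFAULT_SIZE_DISTRIBUTION = {6: 0.15, 12: 0.25, 20: 0.30, 30: 0.20, 45: 0.10}

DEFAULT_CORRUPTION_KINDS = ("abbreviation", "punctuation", "suffix_drop", "reorder", "case")
# Corruptions that a well-behaved name normaliser must survive.
MATCH_SAFE_CORRUPTIONS = ("abbreviation", "punctuation", "suffix_drop", "case")

FIXTURE_FILES = ("patients", "addresses", "households", "register", "events", "ground_truth")

_PRIVATE_HOUSEHOLD_SIZES = ((1, 2, 3, 4, 5), (0.25, 0.40, 0.18, 0.12, 0.05))
_ELDER_HOUSEHOLD_SIZES = ((1, 2, 3, 4, 5), (0.30, 0.65, 0.046, 0.003, 0.001))
_PROP_AGED_65PLUS = 0.35  # share of the registered population aged 65+


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study population.

    Defaults are chosen so the downstream prevalence of identified residents
    among the 65+ population lands in the 2-3.5% band observed in English
    primary-care data, with roughly half of true residents carrying a
    care-home code.
    """

    n_patients: int = 20_000
    n_care_homes: int = 40
    prop_resident_65plus: float = 0.03
    care_home_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DISTRIBUTION)
    )
    p_historical_home: float = 0.10
    p_stale_address: float = 0.25
    p_name_variant: float = 0.10
    p_per_resident_records: float = 0.25
    p_coded_given_resident: float = 0.55
    p_coded_given_nonresident: float = 0.002
    p_temporary_stay: float = 0.10
    p_invalid_household: float = 0.01
    p_shared_postcode: float = 0.05
    demographics_odds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS_ODDS)
    )
    corruption_kinds: tuple[str, ...] = DEFAULT_CORRUPTION_KINDS
    index_date: _dt.date = _dt.date(2020, 2, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.n_care_homes < 0:
            raise ConfigurationError("n_care_homes must be >= 0")
        for name in (
            "prop_resident_65plus",
            "p_historical_home",
            "p_stale_address",
            "p_name_variant",
            "p_per_resident_records",
            "p_coded_given_resident",
            "p_coded_given_nonresident",
            "p_temporary_stay",
            "p_invalid_household",
            "p_shared_postcode",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        dist = self.care_home_size_distribution
        if not dist:
            raise ConfigurationError("care_home_size_distribution must be non-empty")
        if any(beds < 1 for beds in dist):
            raise ConfigurationError("care_home_size_distribution bed counts must be >= 1")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ConfigurationError("care_home_size_distribution probabilities must sum to 1")
        for key, value in self.demographics_odds.items():
            if value <= 0:
                raise ConfigurationError(f"demographics_odds[{key!r}] must be positive")
        unknown = set(self.corruption_kinds) - set(DEFAULT_CORRUPTION_KINDS)
        if unknown:
            raise ConfigurationError(f"corruption_kinds contains unknown kinds: {sorted(unknown)}")

    @property
    def index_ts(self) -> pd.Timestamp:
        return as_timestamp(self.index_date)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["index_date"] = str(self.index_date)
        out["care_home_size_distribution"] = {
            str(k): v for k, v in dict(self.care_home_size_distribution).items()
        }
        out["corruption_kinds"] = list(self.corruption_kinds)
        return out


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _odds_to_prob(base: float, odds_ratio: float) -> float:
    odds = odds_ratio * base / (1.0 - base)
    return odds / (1.0 + odds)


# --------------------------------------------------------------------------
# Postcodes and name banks
# --------------------------------------------------------------------------

def _postcode(i: int) -> str:
    """A unique synthetic postcode with a realistic outward/inward shape."""
    outward = (
        chr(65 + (i // 26) % 26)
        + chr(65 + i % 26)
        + str(1 + (i // 676) % 99)
    )
    inward = f"{1 + i % 9}{chr(65 + (i * 7) % 26)}{chr(65 + (i * 13) % 26)}"
    return f"{outward} {inward}"


_CARE_ADJECTIVES = (
    "Oak", "Rose", "Cedar", "Willow", "Meadow", "Orchard", "High", "Ivy", "Elm",
    "Birch", "Maple", "Holly", "Lavender", "Primrose", "Bluebell", "Hazel",
    "Chestnut", "Ash", "Poppy", "Heather", "Fern", "Juniper", "Laurel", "Magnolia",
)
_CARE_NOUNS = ("Lodge", "Court", "Grange", "Manor", "View", "Gardens", "Park", "Hall", "Place")
_SAINTS = ("Mary", "John", "Anne", "George", "Clare", "Peter", "Helen", "Luke")
_CARE_SUFFIXES = ("Care Home", "Nursing Home", "Residential Home", "")
_PRIVATE_NAMES = (
    "Rose Cottage", "Fern Cottage", "Wisteria Cottage", "Hill Crest", "Sunny Side",
    "The Old Forge", "Honeysuckle Cottage", "Mill Cottage", "Bramble Cottage", "Spring Bank",
)


def _care_home_names(n: int, rng: np.random.Generator) -> list[str]:
    roots = [f"{a} {b}" for a, b in itertools.product(_CARE_ADJECTIVES, _CARE_NOUNS)]
    roots += [f"Saint {s}s" for s in _SAINTS]
    order = rng.permutation(len(roots))
    names = []
    for k in range(n):
        root = roots[order[k % len(roots)]]
        if k >= len(roots):  # pool exhausted: disambiguate with a numeral token
            root = f"{root} {k // len(roots) + 1}"
        suffix = _CARE_SUFFIXES[rng.integers(0, len(_CARE_SUFFIXES))]
        names.append(f"{root} {suffix}".strip())
    return names


# --------------------------------------------------------------------------
# Name corruption
# --------------------------------------------------------------------------

_ABBREVIATE = (("Saint", "St"), ("House", "Hse"), ("Road", "Rd"))
_DROPPABLE_SUFFIXES = ("Care Home", "Nursing Home", "Residential Home", "Home")


def corrupt_name(
    name: str,
    rng: np.random.Generator,
    kinds: tuple[str, ...] = DEFAULT_CORRUPTION_KINDS,
) -> tuple[str, str]:
    """Apply one corruption to a building name; returns (text, kind applied).

    Kinds: ``abbreviation`` (Saint -> St etc.), ``punctuation`` (inserted
    periods/apostrophes), ``suffix_drop`` (generic trailing "Care Home"
    removed), ``reorder`` (first two tokens swapped — the only kind a
    normalising matcher is *not* expected to survive), ``case``. When the
    drawn kind does not apply to the name, the case change is used instead.
    """
    if not name:
        raise ValueError("cannot corrupt an empty name")
    kind = kinds[rng.integers(0, len(kinds))]

    if kind == "abbreviation":
        for full, abbrev in _ABBREVIATE:
            if full in name.split():
                tokens = [abbrev if t == full else t for t in name.split()]
                return " ".join(tokens), kind
        kind = "case"
    if kind == "punctuation":
        tokens = name.split()
        tokens[0] = tokens[0] + "."
        for i, token in enumerate(tokens):
            if len(token) > 3 and token.endswith("s") and not token.endswith("'s"):
                tokens[i] = token[:-1] + "'s"
                break
        return " ".join(tokens), kind
    if kind == "suffix_drop":
        for suffix in _DROPPABLE_SUFFIXES:
            if name.endswith(" " + suffix):
                return name[: -len(suffix) - 1], kind
        kind = "case"
    if kind == "reorder":
        tokens = name.split()
        if len(tokens) >= 2:
            tokens[0], tokens[1] = tokens[1], tokens[0]
            return " ".join(tokens), kind
        kind = "case"
    # case change (also the fallback for inapplicable kinds)
    return (name.upper() if rng.random() < 0.5 else name.lower()), "case"


# --------------------------------------------------------------------------
# Register
# --------------------------------------------------------------------------

REGISTER_COLUMNS = [
    "location_id", "postcode", "building_name", "requires_nursing",
    "does_not_require_nursing", "registered_from", "registered_to",
    "old_age_home", "beds",
]


def generate_register(config: GeneratorConfig) -> pd.DataFrame:
    """A CQC-style register of care-home locations.

    A configurable fraction of homes are historically registered (their
    registration ends before the index date); bed counts follow the
    configured size distribution; nursing-requirement flags cover the
    nursing / non-nursing / neither / (rare, contradictory) both-Y patterns.
    """
    n = config.n_care_homes
    if n == 0:
        return pd.DataFrame(columns=REGISTER_COLUMNS)
    rng = _rng(config, 1)
    index_ts = config.index_ts

    names = _care_home_names(n, rng)
    postcodes = [_postcode(i) for i in range(n)]
    beds_values = np.array(sorted(config.care_home_size_distribution), dtype=int)
    beds_probs = np.array([config.care_home_size_distribution[b] for b in beds_values])
    beds = rng.choice(beds_values, size=n, p=beds_probs / beds_probs.sum())

    historical = rng.random(n) < config.p_historical_home
    opened_days_ago = rng.integers(2 * 365, 25 * 365, size=n)
    registered_from = index_ts - pd.to_timedelta(opened_days_ago, unit="D")
    closed_days_ago = rng.integers(1, 2 * 365, size=n)
    registered_to = pd.Series([pd.NaT] * n)
    registered_to[historical] = index_ts - pd.to_timedelta(closed_days_ago[historical], unit="D")

    nursing_kind = rng.choice(
        ["no_nursing", "nursing", "neither", "both"], size=n, p=[0.45, 0.45, 0.08, 0.02]
    )
    requires = np.where(np.isin(nursing_kind, ["nursing", "both"]), "Y", "N")
    does_not = np.where(np.isin(nursing_kind, ["no_nursing", "both"]), "Y", "N")
    old_age = rng.random(n) < 0.9

    return pd.DataFrame(
        {
            "location_id": [f"CH{i:05d}" for i in range(1, n + 1)],
            "postcode": postcodes,
            "building_name": names,
            "requires_nursing": requires,
            "does_not_require_nursing": does_not,
            "registered_from": registered_from,
            "registered_to": registered_to,
            "old_age_home": old_age,
            "beds": beds,
        }
    )


# --------------------------------------------------------------------------
# Population
# --------------------------------------------------------------------------

def _draw_flag(
    rng: np.random.Generator, resident: np.ndarray, base: float, odds_ratio: float
) -> np.ndarray:
    p = np.where(resident, _odds_to_prob(base, odds_ratio), base)
    return rng.random(len(resident)) < p


def generate_population(
    config: GeneratorConfig, register: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, addresses, households, ground_truth).

    True residents are placed at care-home addresses: residents of one home
    share the home's household id, and (unless the home keeps per-resident
    address records) a single address record. A ``p_stale_address`` fraction
    of permanent residents — and all temporary-stay residents — remain
    registered at a private address instead. Invalid household ids are
    encoded as 0.
    """
    rng = _rng(config, 2)
    index_ts = config.index_ts
    n = config.n_patients

    is65 = rng.random(n) < _PROP_AGED_65PLUS
    resident = is65 & (rng.random(n) < config.prop_resident_65plus)
    if resident.any():
        if register.empty:
            raise GenerationError("residents requested but the care-home register is empty")
        active = register[
            (register["registered_to"].isna() | (register["registered_to"] >= index_ts))
            & (register["registered_from"] <= index_ts)
        ]
        homes = active[active["old_age_home"].astype(bool)].reset_index(drop=True)
        if homes.empty:
            raise GenerationError("residents requested but no active old-age home in the register")
    else:
        homes = register.iloc[0:0]

    # --- demographics ---------------------------------------------------
    odds = dict(DEFAULT_DEMOGRAPHICS_ODDS)
    odds.update(config.demographics_odds)
    female = np.where(
        is65,
        _draw_flag(rng, resident, BASE_RATES_65PLUS["female"], odds["female"]),
        rng.random(n) < _BASE_RATES_UNDER65["female"],
    )
    over80 = is65 & _draw_flag(rng, resident, BASE_RATES_65PLUS["over_80"], odds["over_80"])
    white = np.where(
        is65,
        _draw_flag(rng, resident, BASE_RATES_65PLUS["white"], odds["white"]),
        rng.random(n) < _BASE_RATES_UNDER65["white"],
    )
    dementia = np.where(
        is65,
        _draw_flag(rng, resident, BASE_RATES_65PLUS["dementia"], odds["dementia"]),
        rng.random(n) < _BASE_RATES_UNDER65["dementia"],
    )
    stroke = np.where(
        is65,
        _draw_flag(rng, resident, BASE_RATES_65PLUS["stroke"], odds["stroke"]),
        rng.random(n) < _BASE_RATES_UNDER65["stroke"],
    )
    ages = np.where(
        is65,
        np.where(over80, rng.integers(81, 96, size=n), rng.integers(65, 81, size=n)),
        rng.integers(18, 65, size=n),
    )
    dob = random_dob_for_age(rng, ages, index_ts)

    # --- residency placement --------------------------------------------
    resident_idx = np.flatnonzero(resident)
    n_res = len(resident_idx)
    temporary = np.zeros(n, dtype=bool)
    stale = np.zeros(n, dtype=bool)
    home_of = np.full(n, -1, dtype=int)
    if n_res:
        # Care homes run close to capacity: fill homes (in random order) to
        # their bed count before opening the next, cycling if residents
        # outnumber beds. Spreading residents thinly would leave every home
        # far below the occupancy real registers show.
        order = rng.permutation(len(homes))
        beds = homes["beds"].to_numpy()
        slots = np.concatenate([np.repeat(order, beds[order])] * (1 + n_res // max(int(beds.sum()), 1)))
        home_of[resident_idx] = slots[:n_res]
        temporary[resident_idx] = rng.random(n_res) < config.p_temporary_stay
        stale[resident_idx] = (~temporary[resident_idx]) & (
            rng.random(n_res) < config.p_stale_address
        )

    placed = resident & ~temporary & ~stale  # registered at the care home

    # --- addresses & households -----------------------------------------
    address_rows: list[dict] = []
    patient_address = np.zeros(n, dtype=int)
    patient_household = np.zeros(n, dtype=int)
    next_address = itertools.count(1)
    next_household = itertools.count(1)
    next_postcode = itertools.count(len(register))
    valid_from = index_ts - pd.Timedelta(days=365 * 3)

    def _home_address_fields(home: pd.Series) -> dict:
        name = home["building_name"]
        corruption = ""
        if rng.random() < config.p_name_variant:
            name, corruption = corrupt_name(name, rng, config.corruption_kinds)
        in_other_text = rng.random() < 0.1
        return {
            "postcode": home["postcode"],
            "house_name": "" if in_other_text else name,
            "other_text": name if in_other_text else "",
            "name_corruption": corruption,
        }

    home_numbers = {
        i: (str(int(rng.integers(1, 121))) if rng.random() < 0.7 else "")
        for i in range(len(homes))
    }

    for home_pos in sorted(set(home_of[placed])):
        home = homes.iloc[home_pos]
        members = np.flatnonzero(placed & (home_of == home_pos))
        household_id = next(next_household)
        per_resident = rng.random() < config.p_per_resident_records
        if per_resident:
            for member in members:
                address_id = next(next_address)
                fields = _home_address_fields(home)
                address_rows.append(
                    {
                        "address_id": address_id,
                        "house_number": home_numbers[home_pos],
                        "valid_from": valid_from,
                        "valid_to": pd.NaT,
                        **fields,
                    }
                )
                patient_address[member] = address_id
        else:
            address_id = next(next_address)
            fields = _home_address_fields(home)
            address_rows.append(
                {
                    "address_id": address_id,
                    "house_number": home_numbers[home_pos],
                    "valid_from": valid_from,
                    "valid_to": pd.NaT,
                    **fields,
                }
            )
            patient_address[members] = address_id
        patient_household[members] = household_id

    def _private_dwelling(members: np.ndarray, allow_shared_postcode: bool) -> None:
        address_id = next(next_address)
        household_id = next(next_household)
        shared = allow_shared_postcode and len(register) and rng.random() < config.p_shared_postcode
        if shared:
            postcode = register["postcode"].iloc[int(rng.integers(0, len(register)))]
        else:
            postcode = _postcode(next(next_postcode))
        house_name = (
            _PRIVATE_NAMES[int(rng.integers(0, len(_PRIVATE_NAMES)))]
            if rng.random() < 0.12
            else ""
        )
        # Within one postcode a house number identifies a single dwelling, so
        # dwellings sharing a care-home postcode draw from a number range
        # disjoint from the care homes' own (1-120).
        number_low, number_high = (121, 321) if shared else (1, 201)
        address_rows.append(
            {
                "address_id": address_id,
                "postcode": postcode,
                "house_name": house_name,
                "other_text": "",
                "house_number": (
                    str(int(rng.integers(number_low, number_high))) if rng.random() < 0.95 else ""
                ),
                "valid_from": valid_from,
                "valid_to": pd.NaT,
                "name_corruption": "",
            }
        )
        patient_address[members] = address_id
        patient_household[members] = household_id

    # Residents whose record was never updated (stale) or whose stay is
    # temporary stay registered at their own private dwelling, away from any
    # care-home postcode.
    for i in np.flatnonzero(resident & (temporary | stale)):
        _private_dwelling(np.array([i]), allow_shared_postcode=False)

    # Non-residents grouped into private households, age-assortatively:
    # over-65s live mostly alone or as couples (large all-elder private
    # households are rare outside institutions, but they do occur and are
    # this rule's main false-positive source); younger households are larger.
    for pool, (sizes, size_probs) in (
        (rng.permutation(np.flatnonzero(~resident & is65)), _ELDER_HOUSEHOLD_SIZES),
        (rng.permutation(np.flatnonzero(~resident & ~is65)), _PRIVATE_HOUSEHOLD_SIZES),
    ):
        cursor = 0
        while cursor < len(pool):
            size = int(rng.choice(sizes, p=size_probs))
            members = pool[cursor : cursor + size]
            cursor += size
            _private_dwelling(members, allow_shared_postcode=True)

    # Invalid household ids (encoded as zero) on a small fraction of patients.
    invalid = rng.random(n) < config.p_invalid_household
    patient_household[invalid] = 0

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "date_of_birth": dob.values,
            "age": ages,
            "sex": np.where(female, "F", "M"),
            "ethnicity_white": white.astype(int),
            "dementia": dementia.astype(int),
            "stroke": stroke.astype(int),
            "address_id": patient_address,
            "household_id": patient_household,
        }
    )
    addresses = pd.DataFrame(
        address_rows,
        columns=[
            "address_id", "postcode", "house_name", "house_number",
            "other_text", "valid_from", "valid_to", "name_corruption",
        ],
    )
    member_counts = pd.Series(patient_household[patient_household != 0]).value_counts().sort_index()
    inflate = rng.random(len(member_counts)) < 0.1
    households = pd.DataFrame(
        {
            "household_id": member_counts.index.to_numpy(),
            "household_size": member_counts.to_numpy()
            + np.where(inflate, rng.integers(1, 3, size=len(member_counts)), 0),
        }
    )
    care_home_ids = np.where(
        resident, homes["location_id"].reindex(home_of).to_numpy(), ""
    ) if n_res else np.array([""] * n, dtype=object)
    ground_truth = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "is_true_resident": resident.astype(int),
            "care_home_id": care_home_ids,
            "stay_type": np.where(resident, np.where(temporary, "temporary", "permanent"), ""),
        }
    )
    return patients, addresses, households, ground_truth


# --------------------------------------------------------------------------
# Coded events
# --------------------------------------------------------------------------

def generate_coded_events(
    config: GeneratorConfig, ground_truth: pd.DataFrame, codelist: Codelist
) -> pd.DataFrame:
    """Dated care-home codes: residents are coded with probability
    ``p_coded_given_resident``, non-residents with ``p_coded_given_nonresident``;
    dates fall 1-1095 days before the index date so both the past-year and
    ever windows are exercised. Incentivised codes are drawn three times as
    often as the rest of the list."""
    if len(codelist) == 0:
        raise ConfigurationError("codelist must be non-empty")
    rng = _rng(config, 3)
    index_ts = config.index_ts

    resident = ground_truth["is_true_resident"].astype(bool).to_numpy()
    p = np.where(resident, config.p_coded_given_resident, config.p_coded_given_nonresident)
    coded = rng.random(len(ground_truth)) < p
    patient_ids = ground_truth.loc[coded, "patient_id"].to_numpy()

    codes = [e.code for e in codelist.entries]
    weights = np.array([3.0 if e.incentivised else 1.0 for e in codelist.entries])
    weights /= weights.sum()

    rows = []
    for pid in patient_ids:
        n_events = 2 if rng.random() < 0.3 else 1
        for _ in range(n_events):
            days_before = int(rng.integers(1, 1096))
            rows.append(
                {
                    "patient_id": pid,
                    "code": codes[int(rng.choice(len(codes), p=weights))],
                    "event_date": index_ts - pd.Timedelta(days=days_before),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "code", "event_date"])


# --------------------------------------------------------------------------
# End-to-end simulation and evaluation against the planted truth
# --------------------------------------------------------------------------

@dataclass
class SimulatedData:
    """The six generated tables plus the configuration that produced them."""

    patients: pd.DataFrame
    addresses: pd.DataFrame
    households: pd.DataFrame
    register: pd.DataFrame
    events: pd.DataFrame
    ground_truth: pd.DataFrame
    config: GeneratorConfig

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in FIXTURE_FILES}


def simulate(config: GeneratorConfig, codelist: Codelist | None = None) -> SimulatedData:
    """Run the full generator: register, population, coded events."""
    codelist = codelist or builtin_codelist("primis")
    register = generate_register(config)
    patients, addresses, households, ground_truth = generate_population(config, register)
    events = generate_coded_events(config, ground_truth, codelist)
    return SimulatedData(
        patients=patients,
        addresses=addresses,
        households=households,
        register=register,
        events=events,
        ground_truth=ground_truth,
        config=config,
    )


def write_fixture_set(data: SimulatedData, out_dir) -> dict[str, Path]:
    """Write the fixture CSVs (patients, addresses, households, register,
    events, ground_truth) with stable column order and ISO dates."""
    from .io import write_tables  # local import to avoid a cycle

    return write_tables(data.tables(), out_dir)


def score_against_truth(
    flags: pd.Series, ground_truth: pd.DataFrame, *, include_temporary: bool = False
) -> dict[str, float]:
    """Sensitivity and PPV of a boolean per-patient flag against the planted truth.

    Temporary stays are excluded from the sensitivity denominator by default
    (no method is expected to detect them) but always count as true positives
    for PPV.
    """
    truth = ground_truth.set_index("patient_id")
    flags = flags.reindex(truth.index).fillna(False).astype(bool)
    is_resident = truth["is_true_resident"].astype(bool)
    eval_set = is_resident if include_temporary else (
        is_resident & truth["stay_type"].eq("permanent")
    )
    n_true = int(eval_set.sum())
    n_flagged = int(flags.sum())
    tp_eval = int((flags & eval_set).sum())
    tp_any = int((flags & is_resident).sum())
    return {
        "sensitivity": tp_eval / n_true if n_true else float("nan"),
        "ppv": tp_any / n_flagged if n_flagged else float("nan"),
        "n_true_residents": n_true,
        "n_flagged": n_flagged,
        "n_true_positives": tp_eval,
    }
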