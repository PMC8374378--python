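"""Address-linkage algorithm: normalisation, matching criteria, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import carehomelink as chl
from carehomelink import address_linkage as al
from carehomelink.errors import DataIntegrityError

from conftest import make_addresses, make_patients, make_register


# --------------------------------------------------------------------------
# Name normalisation
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        ("The Willows Care Home", ("WILLOWS",)),
        ("St. Mary's", ("SAINT", "MARYS")),
        ("Saint Marys", ("SAINT", "MARYS")),
        ("Oak Hse Rd", ("OAK", "HOUSE", "ROAD")),
        ("  the   CARE  home ", ()),
        ("", ()),
        (None, ()),
    ],
)
def test_normalization_examples(raw, expected):
    assert chl.normalize_building_name(raw) == expected


def test_normalization_canonicalises_abbreviations_both_ways():
    assert chl.normalized_name_key("St Marys Hse") == chl.normalized_name_key("Saint Mary's House")


@given(st.text(max_size=40))
@settings(derandomize=True, max_examples=200)
def test_normalization_is_deterministic_and_idempotent(text):
    tokens = chl.normalize_building_name(text)
    assert tokens == chl.normalize_building_name(text)
    # normalising an already-normalised name changes nothing
    assert chl.normalize_building_name(" ".join(tokens)) == tokens


def test_normalised_equality_is_an_equivalence_relation():
    """Brute-force pairwise check on a generated corpus of names."""
    rng = np.random.default_rng(5)
    base = [
        f"{a} {b} {c}"
        for a, b, c in itertools.product(
            ["Saint Marys", "St. Mary's", "Oak Lodge", "The Willows"],
            ["Care Home", "Nursing Home", ""],
            ["", "Road", "Rd"],
        )
    ]
    corpus = base + [chl.corrupt_name(n, rng)[0] for n in base if n.strip()]
    keys = [chl.normalized_name_key(n) for n in corpus]
    related = np.array([[a == b for b in keys] for a in keys], dtype=bool)
    assert related.diagonal().all()  # reflexive
    assert (related == related.T).all()  # symmetric
    reach = related.astype(int) @ related.astype(int)  # two-step reachability
    assert ((reach > 0) <= related).all()  # transitive


# --------------------------------------------------------------------------
# Postcode superset match
# --------------------------------------------------------------------------

def _brute_force_postcode(addresses, register):
    pairs = set()
    for _, addr in addresses.iterrows():
        if not str(addr["postcode"]).strip():
            continue
        for _, loc in register.iterrows():
            if addr["postcode"] == loc["postcode"]:
                pairs.add((addr["address_id"], loc["location_id"]))
    return pairs


def test_postcode_match_unmatched_register_gives_empty():
    addresses = make_addresses([(1, "AA1 1AA", "", "1")])
    register = make_register([("CH1", "ZZ9 9ZZ", "Oak Lodge")])
    assert chl.match_postcode(addresses, register).empty


def test_postcode_match_includes_private_homes_on_shared_postcode():
    """The postcode stage is deliberately a superset of true residents."""
    addresses = make_addresses([(1, "AA1 1AA", "Oak Lodge", ""), (2, "AA1 1AA", "", "7")])
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge")])
    pairs = chl.match_postcode(addresses, register)
    assert set(pairs["address_id"]) == {1, 2}


def test_postcode_match_equals_brute_force_on_generated_data(default_sim):
    addresses = default_sim.addresses.sample(500, random_state=0)
    register = default_sim.register
    fast = set(map(tuple, chl.match_postcode(addresses, register).values))
    assert fast == _brute_force_postcode(addresses, register)


# --------------------------------------------------------------------------
# Criterion a: house names
# --------------------------------------------------------------------------

def test_house_name_match_applies_normalisation_rules():
    addresses = make_addresses([(1, "AA1 1AA", "The Willows Care Home", "")])
    register = make_register([("CH1", "AA1 1AA", "Willows")])
    candidates = chl.match_postcode(addresses, register)
    assert len(chl.match_house_name(candidates, addresses, register)) == 1


def test_house_name_requires_postcode_gate():
    addresses = make_addresses([(1, "BB2 2BB", "The Willows Care Home", "")])
    register = make_register([("CH1", "AA1 1AA", "Willows")])
    candidates = chl.match_postcode(addresses, register)
    assert chl.match_house_name(candidates, addresses, register).empty


def test_house_name_falls_back_to_other_text():
    addresses = make_addresses([(1, "AA1 1AA", "", "")])
    addresses.loc[0, "other_text"] = "Willows Care Home"
    register = make_register([("CH1", "AA1 1AA", "Willows")])
    candidates = chl.match_postcode(addresses, register)
    assert len(chl.match_house_name(candidates, addresses, register)) == 1


def test_clean_fixture_every_named_resident_flagged_no_nonresident(clean_sim, index_date):
    data = clean_sim
    classification = chl.classify_address_linkage(
        data.patients, data.addresses, data.register, index_date=index_date
    )
    flags = chl.flags_from_classification(classification)
    scores = chl.score_against_truth(flags, data.ground_truth)
    assert scores["sensitivity"] == 1.0
    assert scores["ppv"] == 1.0


# --------------------------------------------------------------------------
# Criterion b: derived house numbers
# --------------------------------------------------------------------------

def _number_fixture(n_records, number="41"):
    addresses = make_addresses(
        [(i, "AA1 1AA", "Oak Lodge", number) for i in range(1, n_records + 1)]
    )
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge")])
    return addresses, register


@pytest.mark.parametrize("n_records, derived", [(12, True), (10, True), (9, False)])
def test_derive_house_numbers_threshold(n_records, derived):
    addresses, register = _number_fixture(n_records)
    result = chl.derive_house_numbers(addresses, register, threshold=10)
    assert (len(result) == 1) == derived
    if derived:
        assert result.iloc[0]["house_number"] == "41"


def test_derived_numbers_monotone_in_threshold(default_sim):
    at10 = chl.derive_house_numbers(default_sim.addresses, default_sim.register, threshold=10)
    at5 = chl.derive_house_numbers(default_sim.addresses, default_sim.register, threshold=5)
    assert set(map(tuple, at10.values)) <= set(map(tuple, at5.values))


def test_match_house_number_examples():
    addresses, register = _number_fixture(12)
    # an extra address in the postcode carrying the derived number, name unknown
    extra = make_addresses([(99, "AA1 1AA", "", "41"), (100, "CC3 3CC", "", "41")])
    addresses = pd.concat([addresses, extra], ignore_index=True)
    candidates = chl.match_postcode(addresses, register)
    derived = chl.derive_house_numbers(addresses, register, threshold=10)
    matched = chl.match_house_number(candidates, addresses, derived)
    assert 99 in set(matched["address_id"])  # same postcode, derived number
    assert 100 not in set(matched["address_id"])  # wrong postcode: never a candidate


def test_match_house_number_equals_brute_force():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(1, 400):
        postcode = f"AA{rng.integers(1, 4)} 1AA"
        name = rng.choice(["Oak Lodge", "Rose Court", ""])
        number = str(rng.integers(1, 5))
        rows.append((i, postcode, name, number))
    addresses = make_addresses(rows)
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge"), ("CH2", "AA2 1AA", "Rose Court")])
    candidates = chl.match_postcode(addresses, register)
    derived = chl.derive_house_numbers(addresses, register, threshold=10)
    fast = set(map(tuple, chl.match_house_number(candidates, addresses, derived).values))

    # brute force: re-derive numbers by explicit counting, then flag by loop
    slow = set()
    for _, loc in register.iterrows():
        key = chl.normalized_name_key(loc["building_name"])
        counts = {}
        for _, addr in addresses.iterrows():
            if (
                addr["postcode"] == loc["postcode"]
                and addr["house_number"]
                and chl.normalized_name_key(addr["house_name"]) == key
            ):
                counts[addr["house_number"]] = counts.get(addr["house_number"], 0) + 1
        good = {num for num, c in counts.items() if c >= 10}
        for _, addr in addresses.iterrows():
            if addr["postcode"] == loc["postcode"] and addr["house_number"] in good:
                slow.add((addr["address_id"], loc["location_id"]))
    assert fast == slow


# --------------------------------------------------------------------------
# Criterion c: household size at the address
# --------------------------------------------------------------------------

def _size_fixture(ages):
    patients = make_patients([(i + 1, age, 1, 1) for i, age in enumerate(ages)])
    addresses = make_addresses([(1, "AA1 1AA", "", "")])
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge")])
    return patients, addresses, register


@pytest.mark.parametrize(
    "ages, expected",
    [
        ([70] * 10, True),  # exactly at threshold
        ([70] * 9, False),  # below threshold
        ([70] * 9 + [64], False),  # a 64-year-old does not count
        ([70] * 9 + [65], True),  # exactly-65 counts
    ],
)
def test_household_size_criterion_boundaries(ages, expected, index_date):
    patients, addresses, register = _size_fixture(ages)
    candidates = chl.match_postcode(addresses, register)
    flagged = chl.match_household_size(
        candidates, patients, addresses, register, index_date, threshold=10
    )
    assert (not flagged.empty) == expected


def test_household_size_ignores_non_old_age_homes(index_date):
    patients, addresses, register = _size_fixture([70] * 12)
    register["old_age_home"] = False
    candidates = chl.match_postcode(addresses, register)
    assert chl.match_household_size(
        candidates, patients, addresses, register, index_date
    ).empty


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def _classify_single(register, **kwargs):
    patients = make_patients([(1, 82, 1, 1)])
    addresses = make_addresses([(1, "AA1 1AA", "Oak Lodge", "")])
    return chl.classify_address_linkage(
        patients, addresses, register, index_date="2020-02-01", **kwargs
    )


def test_postcode_match_alone_is_private_home():
    patients = make_patients([(1, 82, 1, 1)])
    addresses = make_addresses([(1, "AA1 1AA", "", "")])
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge")])
    result = chl.classify_address_linkage(
        patients, addresses, register, index_date="2020-02-01"
    )
    assert result.iloc[0]["status"] == chl.PRIVATE_HOME
    assert result.iloc[0]["evidence"] == ""


def test_nursing_flags_determine_category():
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge")])
    register.loc[0, ["requires_nursing", "does_not_require_nursing"]] = ["Y", "N"]
    assert _classify_single(register).iloc[0]["status"] == chl.CARE_HOME_NURSING
    register.loc[0, ["requires_nursing", "does_not_require_nursing"]] = ["N", "Y"]
    assert _classify_single(register).iloc[0]["status"] == chl.CARE_HOME_NO_NURSING
    register.loc[0, ["requires_nursing", "does_not_require_nursing"]] = ["Y", "Y"]
    assert _classify_single(register).iloc[0]["status"] == chl.CARE_HOME_MISC


def test_registration_ended_before_index_date_is_private_home():
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge")])
    register.loc[0, "registered_to"] = pd.Timestamp("2019-06-30")
    assert _classify_single(register).iloc[0]["status"] == chl.PRIVATE_HOME


def test_under_65_matches_are_private_home_by_default():
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge")])
    patients = make_patients([(1, 40, 1, 1)])
    addresses = make_addresses([(1, "AA1 1AA", "Oak Lodge", "")])
    result = chl.classify_address_linkage(
        patients, addresses, register, index_date="2020-02-01"
    )
    assert result.iloc[0]["status"] == chl.PRIVATE_HOME
    unrestricted = chl.classify_address_linkage(
        patients, addresses, register, index_date="2020-02-01", restrict_to_min_age=False
    )
    assert unrestricted.iloc[0]["status"] != chl.PRIVATE_HOME


def test_dangling_address_key_raises():
    patients = make_patients([(1, 82, 999, 1)])
    addresses = make_addresses([(1, "AA1 1AA", "", "")])
    register = make_register([("CH1", "AA1 1AA", "Oak Lodge")])
    with pytest.raises(DataIntegrityError, match="999"):
        chl.classify_address_linkage(patients, addresses, register, index_date="2020-02-01")


def test_classification_invariants_on_generated_data(default_sim, index_date):
    data = default_sim
    result = chl.classify_address_linkage(
        data.patients, data.addresses, data.register, index_date=index_date
    )
    # evidence non-empty iff not private_home
    private = result["status"] == chl.PRIVATE_HOME
    assert (result.loc[private, "evidence"] == "").all()
    assert (result.loc[~private, "evidence"] != "").all()
    # gate property: every flagged patient's postcode is a register postcode
    flagged = result[~private].merge(
        data.patients[["patient_id", "address_id"]], on="patient_id"
    ).merge(data.addresses[["address_id", "postcode"]], on="address_id")
    assert flagged["postcode"].isin(set(data.register["postcode"])).all()


def test_classification_is_row_order_invariant(default_sim, index_date):
    data = default_sim
    base = chl.classify_address_linkage(
        data.patients, data.addresses, data.register, index_date=index_date
    )
    shuffled = chl.classify_address_linkage(
        data.patients.sample(frac=1, random_state=7),
        data.addresses.sample(frac=1, random_state=8),
        data.register.sample(frac=1, random_state=9),
        index_date=index_date,
    )
    merged = base.merge(shuffled, on="patient_id", suffixes=("_a", "_b"))
    assert (merged["status_a"] == merged["status_b"]).all()
    assert (merged["evidence_a"] == merged["evidence_b"]).all()


def test_enlarging_register_never_unflags(default_sim, index_date):
    data = default_sim
    half_register = data.register.iloc[: len(data.register) // 2]
    small = chl.flags_from_classification(
        chl.classify_address_linkage(
            data.patients, data.addresses, half_register, index_date=index_date
        )
    )
    full = chl.flags_from_classification(
        chl.classify_address_linkage(
            data.patients, data.addresses, data.register, index_date=index_date
        )
    )
    assert (full[small] | ~small[small]).all()  # every small-register flag survives


def test_raising_thresholds_never_adds_flags(default_sim, index_date):
    data = default_sim
    loose = chl.flags_from_classification(
        chl.classify_address_linkage(
            data.patients, data.addresses, data.register,
            index_date=index_date, size_threshold=5, number_threshold=5,
        )
    )
    strict = chl.flags_from_classification(
        chl.classify_address_linkage(
            data.patients, data.addresses, data.register,
            index_date=index_date, size_threshold=15, number_threshold=15,
        )
    )
    assert (strict <= loose).all()
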