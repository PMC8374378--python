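import pandas as pd
import pytest

import carehomelink as chl

INDEX_DATE = "2020-02-01"


@pytest.fixture(scope="session")
def index_date():
    return INDEX_DATE


@pytest.fixture(scope="session")
def default_sim():
    """A mid-size population under the default error structure."""
    config = chl.GeneratorConfig(n_patients=20_000, n_care_homes=30, seed=11)
    return chl.simulate(config)


@pytest.fixture(scope="session")
def clean_sim():
    """The clean-data limit: no stale addresses, no name corruption, no
    temporary stays; every record should be recoverable."""
    config = chl.GeneratorConfig(
        n_patients=20_000,
        n_care_homes=30,
        seed=12,
        p_stale_address=0.0,
        p_name_variant=0.0,
        p_temporary_stay=0.0,
    )
    return chl.simulate(config)


@pytest.fixture(scope="session")
def default_flags(default_sim, index_date):
    """Method flags for the default simulation's 65+ analysis population."""
    data = default_sim
    classification = chl.classify_address_linkage(
        data.patients, data.addresses, data.register, index_date=index_date
    )
    address = chl.flags_from_classification(classification)
    household = chl.classify_household_rule(
        data.patients, data.households, index_date=index_date
    )
    coded = chl.classify_coded_events(
        data.events,
        chl.builtin_codelist("primis"),
        index_date=index_date,
        patient_ids=data.patients["patient_id"],
    )
    population = chl.restrict_population(data.patients, index_date)
    return chl.assemble_method_flags(population, address, household, coded)


def make_patients(rows):
    """Patients from (patient_id, age, address_id, household_id) tuples."""
    frame = pd.DataFrame(rows, columns=["patient_id", "age", "address_id", "household_id"])
    frame["sex"] = "F"
    frame["ethnicity_white"] = 1
    frame["dementia"] = 0
    frame["stroke"] = 0
    return frame


def make_register(rows):
    """Register from (location_id, postcode, building_name) tuples, active and
    old-age by default; nursing flags N/Y (no nursing)."""
    frame = pd.DataFrame(rows, columns=["location_id", "postcode", "building_name"])
    frame["requires_nursing"] = "N"
    frame["does_not_require_nursing"] = "Y"
    frame["registered_from"] = pd.Timestamp("2010-01-01")
    frame["registered_to"] = pd.NaT
    frame["old_age_home"] = True
    return frame


def make_addresses(rows):
    """Addresses from (address_id, postcode, house_name, house_number) tuples."""
    frame = pd.DataFrame(rows, columns=["address_id", "postcode", "house_name", "house_number"])
    frame["other_text"] = ""
    frame["valid_from"] = pd.Timestamp("2015-01-01")
    frame["valid_to"] = pd.NaT
    return frame
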