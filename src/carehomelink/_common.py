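"""Small shared helpers: date coercion, age arithmetic, half-up rounding."""

from __future__ import annotations

import datetime as _dt
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd


def as_timestamp(value) -> pd.Timestamp:
    """Coerce a date-like value (str, date, datetime, Timestamp) to a Timestamp."""
    ts = pd.Timestamp(value)
    if ts is pd.NaT:
        raise ValueError(f"not a date: {value!r}")
    return ts


def age_at(patients: pd.DataFrame, index_date) -> pd.Series:
    """Completed years of age at ``index_date``, indexed like ``patients``.

    Uses ``date_of_birth`` when present; otherwise falls back on a
    pre-computed ``age`` column (taken to be the age at the index date).
    """
    index_ts = as_timestamp(index_date)
    if "date_of_birth" in patients.columns:
        dob = pd.to_datetime(patients["date_of_birth"])
        years = index_ts.year - dob.dt.year
        before_birthday = (dob.dt.month > index_ts.month) | (
            (dob.dt.month == index_ts.month) & (dob.dt.day > index_ts.day)
        )
        return (years - before_birthday.astype(int)).astype(int)
    if "age" in patients.columns:
        return patients["age"].astype(int)
    raise SchemaLikeKeyError("patients table has neither date_of_birth nor age")


class SchemaLikeKeyError(KeyError):
    pass


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimal places.

    Published prevalence/overlap tables round half-up, which differs from
    Python's banker's rounding at exact ties.
    """
    if value != value:  # NaN
        return float("nan")
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def year_before(index_date) -> pd.Timestamp:
    """The same calendar date one year earlier; 29 Feb maps to 28 Feb."""
    ts = as_timestamp(index_date)
    return ts - pd.DateOffset(years=1)


def clean_number_token(value) -> str | None:
    """Normalise a house-number cell to a plain string token (``41.0`` -> ``"41"``)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    token = str(value).strip()
    if not token or token.lower() == "nan":
        return None
    if token.endswith(".0"):
        token = token[:-2]
    return token


def random_dob_for_age(rng: np.random.Generator, ages: np.ndarray, index_date) -> pd.Series:
    """Dates of birth consistent with completed ``ages`` at ``index_date``.

    Month/day are drawn uniformly (days capped at 28 to stay valid in every
    month); the birth year is then fixed so that ``age_at`` inverts exactly.
    """
    index_ts = as_timestamp(index_date)
    n = len(ages)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    birthday_passed = (months < index_ts.month) | ((months == index_ts.month) & (days <= index_ts.day))
    years = index_ts.year - ages - np.where(birthday_passed, 0, 1)
    return pd.to_datetime(
        pd.Series([_dt.date(int(y), int(m), int(d)) for y, m, d in zip(years, months, days)])
    )
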