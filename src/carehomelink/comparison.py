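"""Descriptive comparison of residency-identification methods.

Given per-patient boolean flags for the three methods (address linkage,
household size/age rule, coded events), this module computes:

* prevalence rows — count and percentage of the analysis population flagged
  by each method, each pairwise union and the three-way union;
* exact three-set Venn region counts, with an inclusion–exclusion
  consistency check on every run;
* overlap statistics — the share of each method's flagged set also flagged
  by at least one other method, the share flagged by all three or by at
  least two, and the share of a method's flagged set lacking coded events;
* a characteristics table (percent male, over-80, white ethnicity, dementia,
  stroke) per flagged set.

All of these are also recomputable from printed marginal counts alone
(method totals plus pairwise and three-way union totals) via
inclusion–exclusion, so a published prevalence table can be fed back through
the same arithmetic.

Percentages round half-up at the requested precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._common import age_at, round_half_up
from .errors import EmptyFlagSetError

logger = logging.getLogger(__name__)

METHODS = ("address_linkage", "household_rule", "coded_events")

__all__ = [
    "METHODS",
    "VennSummary",
    "OverlapCounts",
    "restrict_population",
    "assemble_method_flags",
    "prevalence_table",
    "prevalence_from_flags",
    "counts_from_flags",
    "venn",
    "overlap_counts_from_flags",
    "overlap_statistics",
    "percent_overlap",
    "characteristics_table",
]


# --------------------------------------------------------------------------
# Analysis population and flag assembly
# --------------------------------------------------------------------------

def restrict_population(patients: pd.DataFrame, index_date, min_age: int = 65) -> pd.DataFrame:
    """The analysis population: patients aged >= ``min_age`` at the index date."""
    ages = age_at(patients, index_date)
    population = patients[ages >= min_age].reset_index(drop=True)
    if population.empty:
        logger.warning("restrict_population: no patients aged >= %d at index date", min_age)
    return population


def assemble_method_flags(
    population: pd.DataFrame,
    address_linkage: pd.Series,
    household_rule: pd.Series,
    coded_events: pd.Series,
) -> pd.DataFrame:
    """One row per analysis-population patient with the three method booleans.

    Each input is a boolean Series indexed by patient_id; patients absent
    from a series are unflagged by that method.
    """
    index = pd.Index(population["patient_id"].values, name="patient_id")
    flags = pd.DataFrame(index=index)
    for name, series in zip(METHODS, (address_linkage, household_rule, coded_events)):
        flags[name] = series.reindex(index).fillna(False).astype(bool)
    return flags.reset_index()


# --------------------------------------------------------------------------
# Prevalence
# --------------------------------------------------------------------------

def prevalence_table(
    counts: Mapping[str, int], total: int, *, precision: int = 2
) -> pd.DataFrame:
    """Rows of (label, count, percent-of-total) for each supplied count.

    ``percent`` is 100*count/total rounded half-up to ``precision`` decimal
    places; the counts themselves are carried through so every percentage is
    reproducible from the emitted table alone.
    """
    if total < 1:
        raise EmptyFlagSetError("prevalence percentages are undefined for an empty population")
    rows = [
        {
            "label": label,
            "count": int(count),
            "percent": round_half_up(100.0 * count / total, precision),
        }
        for label, count in counts.items()
    ]
    return pd.DataFrame(rows, columns=["label", "count", "percent"])


def counts_from_flags(flags: pd.DataFrame) -> dict[str, int]:
    """Method, pairwise-union and any-method counts from a flag frame."""
    a, h, c = (flags[m].astype(bool) for m in METHODS)
    return {
        "address_linkage": int(a.sum()),
        "household_rule": int(h.sum()),
        "coded_events": int(c.sum()),
        "address_linkage_or_household_rule": int((a | h).sum()),
        "address_linkage_or_coded_events": int((a | c).sum()),
        "household_rule_or_coded_events": int((h | c).sum()),
        "any_method": int((a | h | c).sum()),
    }


def prevalence_from_flags(
    flags: pd.DataFrame, total: int | None = None, *, precision: int = 2
) -> pd.DataFrame:
    """Prevalence table straight from flags; ``total`` defaults to len(flags)."""
    return prevalence_table(counts_from_flags(flags), total or len(flags), precision=precision)


# --------------------------------------------------------------------------
# Venn regions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VennSummary:
    """Exact counts of the 8 regions of the three-method Venn diagram.

    Region keys are (address_linkage, household_rule, coded_events) boolean
    triples; the 8 counts partition the population.
    """

    regions: Mapping[tuple[bool, bool, bool], int]
    population: int

    def __post_init__(self) -> None:
        if sum(self.regions.values()) != self.population:
            raise ValueError("venn regions must partition the population")
        for method_index, method in enumerate(METHODS):
            total = self.method_total(method)
            region_sum = sum(
                n for key, n in self.regions.items() if key[method_index]
            )
            assert total == region_sum  # by construction

    def method_total(self, method: str) -> int:
        i = METHODS.index(method)
        return sum(n for key, n in self.regions.items() if key[i])

    @property
    def union(self) -> int:
        return self.population - self.regions.get((False, False, False), 0)

    @property
    def triple(self) -> int:
        return self.regions.get((True, True, True), 0)

    def n_flagged_by_at_least(self, k: int) -> int:
        return sum(n for key, n in self.regions.items() if sum(key) >= k)

    def pairwise(self, m1: str, m2: str) -> int:
        i, j = METHODS.index(m1), METHODS.index(m2)
        return sum(n for key, n in self.regions.items() if key[i] and key[j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.regions, reverse=True):
            label = "&".join(m for m, flag in zip(METHODS, key) if flag) or "none"
            rows.append({"region": label, "count": self.regions[key]})
        return pd.DataFrame(rows)


def venn(flags: pd.DataFrame) -> VennSummary:
    """Count the 8 Venn regions of the three method flags exactly."""
    cols = [flags[m].astype(bool) for m in METHODS]
    grouped = pd.DataFrame({m: c.values for m, c in zip(METHODS, cols)}).groupby(list(METHODS)).size()
    regions = {
        (bool(a), bool(h), bool(c)): 0 for a in (0, 1) for h in (0, 1) for c in (0, 1)
    }
    for key, count in grouped.items():
        regions[tuple(bool(v) for v in key)] = int(count)
    summary = VennSummary(regions=regions, population=len(flags))
    _check_inclusion_exclusion(summary)
    return summary


def _check_inclusion_exclusion(v: VennSummary) -> None:
    """|A∪B∪C| = Σ singles − Σ pairwise + triple must hold exactly."""
    singles = sum(v.method_total(m) for m in METHODS)
    pairs = (
        v.pairwise(METHODS[0], METHODS[1])
        + v.pairwise(METHODS[0], METHODS[2])
        + v.pairwise(METHODS[1], METHODS[2])
    )
    if v.union != singles - pairs + v.triple:
        raise AssertionError("inclusion-exclusion identity violated; flag frame inconsistent")


# --------------------------------------------------------------------------
# Overlap statistics (from flags or from printed marginal counts)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapCounts:
    """Marginal counts sufficient to recover all intersections.

    These are exactly the counts a published prevalence table prints: the
    three method totals, the three pairwise-union totals and the three-way
    union, plus the population total.
    """

    address_linkage: int
    household_rule: int
    coded_events: int
    address_linkage_or_household_rule: int
    address_linkage_or_coded_events: int
    household_rule_or_coded_events: int
    any_method: int
    total: int

    def intersections(self) -> dict[str, int]:
        """Pairwise and triple intersections via inclusion–exclusion."""
        ah = self.address_linkage + self.household_rule - self.address_linkage_or_household_rule
        ac = self.address_linkage + self.coded_events - self.address_linkage_or_coded_events
        hc = self.household_rule + self.coded_events - self.household_rule_or_coded_events
        triple = (
            self.any_method
            - (self.address_linkage + self.household_rule + self.coded_events)
            + (ah + ac + hc)
        )
        return {
            "address_linkage_and_household_rule": ah,
            "address_linkage_and_coded_events": ac,
            "household_rule_and_coded_events": hc,
            "all_three": triple,
            "at_least_two": ah + ac + hc - 2 * triple,
        }


def overlap_counts_from_flags(flags: pd.DataFrame) -> OverlapCounts:
    counts = counts_from_flags(flags)
    return OverlapCounts(total=len(flags), **counts)


def overlap_statistics(
    counts: OverlapCounts,
    *,
    precision_overlap: int = 1,
    precision_lacking: int = 0,
) -> dict[str, float]:
    """The overlap summary the three-method comparison reports.

    Per-method overlap = share of the method's flagged set also flagged by at
    least one other method (printed at 1 dp); ``*_lacking_coded_events_pct``
    = share of the method's flagged set without a qualifying coded event
    (printed at 0 dp); plus the share of the union flagged by all three and
    by at least two methods (1 dp).
    """
    inter = counts.intersections()
    a, h, c = counts.address_linkage, counts.household_rule, counts.coded_events
    union = counts.any_method
    if union < 1:
        raise EmptyFlagSetError("overlap statistics undefined: no patient flagged by any method")

    def _pct(numerator: int, denominator: int, precision: int) -> float:
        if denominator < 1:
            raise EmptyFlagSetError("overlap percentage undefined over an empty flagged set")
        return round_half_up(100.0 * numerator / denominator, precision)

    # |A ∩ (H ∪ C)| = |A| − (|A∪H∪C| − |H∪C|), and cyclically.
    a_overlap = a - (union - counts.household_rule_or_coded_events)
    h_overlap = h - (union - counts.address_linkage_or_coded_events)
    c_overlap = c - (union - counts.address_linkage_or_household_rule)

    return {
        "all_three_methods_pct": _pct(inter["all_three"], union, precision_overlap),
        "at_least_two_methods_pct": _pct(inter["at_least_two"], union, precision_overlap),
        "address_linkage_overlap_pct": _pct(a_overlap, a, precision_overlap),
        "household_rule_overlap_pct": _pct(h_overlap, h, precision_overlap),
        "coded_events_overlap_pct": _pct(c_overlap, c, precision_overlap),
        "address_linkage_lacking_coded_events_pct": _pct(
            a - inter["address_linkage_and_coded_events"], a, precision_lacking
        ),
        "household_rule_lacking_coded_events_pct": _pct(
            h - inter["household_rule_and_coded_events"], h, precision_lacking
        ),
        "all_three_methods_count": inter["all_three"],
        "at_least_two_methods_count": inter["at_least_two"],
    }


def percent_overlap(
    flags: pd.DataFrame,
    method: str,
    *,
    precision_overlap: int = 1,
    precision_lacking: int = 0,
) -> dict[str, float]:
    """For one method: share of its flagged set also flagged by another
    method, and share lacking coded events. Errors on an empty flagged set."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")
    flagged = flags[flags[method].astype(bool)]
    if flagged.empty:
        raise EmptyFlagSetError(f"no patient flagged by {method}; overlap undefined")
    others = [m for m in METHODS if m != method]
    overlap = (flagged[others[0]].astype(bool) | flagged[others[1]].astype(bool)).sum()
    lacking = (~flagged["coded_events"].astype(bool)).sum()
    return {
        "overlap_pct": round_half_up(100.0 * overlap / len(flagged), precision_overlap),
        "lacking_coded_events_pct": round_half_up(
            100.0 * lacking / len(flagged), precision_lacking
        ),
    }


# --------------------------------------------------------------------------
# Characteristics of flagged patients
# --------------------------------------------------------------------------

DEFAULT_CHARACTERISTICS = ("male", "over_80", "white", "dementia", "stroke")


def _characteristic_indicators(
    patients: pd.DataFrame, index_date, names: Sequence[str]
) -> pd.DataFrame:
    ages = age_at(patients, index_date)
    available = {
        "male": lambda: patients["sex"].astype(str).str.upper().eq("M"),
        "over_80": lambda: ages > 80,
        "white": lambda: patients["ethnicity_white"].astype(bool),
        "dementia": lambda: patients["dementia"].astype(bool),
        "stroke": lambda: patients["stroke"].astype(bool),
    }
    frame = pd.DataFrame(index=patients["patient_id"].values)
    for name in names:
        frame[name] = available[name]().values
    return frame


def characteristics_table(
    flags: pd.DataFrame,
    patients: pd.DataFrame,
    *,
    index_date,
    characteristics: Sequence[str] = DEFAULT_CHARACTERISTICS,
    precision: int = 1,
) -> pd.DataFrame:
    """Percent of each flagged set (and of the whole population) with each
    characteristic; empty flagged sets yield NaN columns, never silent zeros."""
    indicators = _characteristic_indicators(patients, index_date, characteristics)
    flag_index = pd.Index(flags["patient_id"].values)
    indicators = indicators.reindex(flag_index)

    columns: dict[str, list[float]] = {}
    groups = {"all": pd.Series(True, index=flag_index)}
    for method in METHODS:
        groups[method] = pd.Series(flags[method].astype(bool).values, index=flag_index)

    for label, mask in groups.items():
        subset = indicators[mask.values]
        if subset.empty:
            logger.warning("characteristics_table: empty flagged set for %s", label)
            columns[label] = [float("nan")] * len(characteristics)
        else:
            columns[label] = [
                round_half_up(100.0 * subset[name].mean(), precision) for name in characteristics
            ]
    out = pd.DataFrame(columns, index=list(characteristics))
    out.index.name = "characteristic"
    return out
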