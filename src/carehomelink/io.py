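"""Readers/writers, run configuration and the end-to-end pipeline.

All tables travel as UTF-8 comma-delimited CSV with a header row and
ISO-8601 dates; the dialect is fixed so fixture files stay bit-stable. A run
is fully described by a :class:`RunConfig` (either paths to existing tables
or a simulate block) and produces an artifact directory with the per-method
classifications, the comparison tables, a data-quality report and a manifest
sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import address_linkage as al
from . import comparison as cmp
from . import rule_classifiers as rc
from . import synthetic
from ._common import as_timestamp
from .errors import ConfigurationError, DataIntegrityError, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["TABLE_SCHEMAS", "read_tables", "write_tables", "RunConfig", "run_pipeline"]

# Required columns per table; extra columns are carried through untouched.
TABLE_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "patients": (
        "patient_id", "date_of_birth", "sex", "ethnicity_white",
        "dementia", "stroke", "address_id", "household_id",
    ),
    "addresses": (
        "address_id", "postcode", "house_name", "house_number",
        "other_text", "valid_from", "valid_to",
    ),
    "households": ("household_id", "household_size"),
    "register": (
        "location_id", "postcode", "building_name", "requires_nursing",
        "does_not_require_nursing", "registered_from", "registered_to", "old_age_home",
    ),
    "events": ("patient_id", "code", "event_date"),
    "ground_truth": ("patient_id", "is_true_resident", "care_home_id", "stay_type"),
}

_DATE_COLUMNS = {
    "patients": ("date_of_birth",),
    "addresses": ("valid_from", "valid_to"),
    "register": ("registered_from", "registered_to"),
    "events": ("event_date",),
}

_STRING_COLUMNS = {
    "addresses": ("postcode", "house_name", "house_number", "other_text"),
    "register": ("location_id", "postcode", "building_name"),
    "events": ("code",),
    "ground_truth": ("care_home_id", "stay_type"),
}


def read_tables(source, *, require_ground_truth: bool = False) -> dict[str, pd.DataFrame]:
    """Read and validate the fixture CSVs from a directory or a name->path mapping.

    Schema violations raise :class:`SchemaError` naming the table and column;
    dangling patient->address / patient->household / ground-truth->register
    keys raise :class:`DataIntegrityError` listing the offending ids. CRLF
    and LF files parse identically.
    """
    if isinstance(source, (str, Path)):
        directory = Path(source)
        paths = {name: directory / f"{name}.csv" for name in TABLE_SCHEMAS}
    else:
        paths = {name: Path(p) for name, p in source.items()}

    tables: dict[str, pd.DataFrame] = {}
    for name, required in TABLE_SCHEMAS.items():
        path = paths.get(name)
        if path is None or not path.exists():
            if name == "ground_truth" and not require_ground_truth:
                continue
            raise SchemaError(f"missing input table {name!r} (expected at {path})")
        frame = pd.read_csv(path, dtype={c: str for c in _STRING_COLUMNS.get(name, ())})
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"table {name!r} is missing column(s): {', '.join(missing)}")
        for column in _DATE_COLUMNS.get(name, ()):
            frame[column] = pd.to_datetime(frame[column], errors="coerce")
        for column in _STRING_COLUMNS.get(name, ()):
            frame[column] = frame[column].fillna("")
        tables[name] = frame

    _check_integrity(tables)
    return tables


def _check_integrity(tables: Mapping[str, pd.DataFrame]) -> None:
    patients = tables["patients"]
    dangling = sorted(set(patients["address_id"]) - set(tables["addresses"]["address_id"]))
    if dangling:
        raise DataIntegrityError(
            f"patients reference unknown address ids: {dangling[:10]}"
            + (" ..." if len(dangling) > 10 else "")
        )
    household_ids = set(tables["households"]["household_id"]) | {rc.INVALID_HOUSEHOLD_ID}
    dangling = sorted(set(patients["household_id"]) - household_ids)
    if dangling:
        raise DataIntegrityError(
            f"patients reference unknown household ids: {dangling[:10]}"
            + (" ..." if len(dangling) > 10 else "")
        )
    if "ground_truth" in tables:
        truth = tables["ground_truth"]
        referenced = set(truth.loc[truth["care_home_id"] != "", "care_home_id"])
        dangling = sorted(referenced - set(tables["register"]["location_id"]))
        if dangling:
            raise DataIntegrityError(f"ground truth references unknown care homes: {dangling[:10]}")


def _atomic_to_csv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        frame.to_csv(tmp, index=False, date_format="%Y-%m-%d", lineterminator="\n")
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write each table atomically as ``<name>.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    written = {}
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        _atomic_to_csv(frame, path)
        written[name] = path
    return written


def _atomic_write_text(text: str, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as handle:
        handle.write(text)
    os.replace(tmp, path)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run.

    Exactly one of ``input_dir`` (pre-existing fixture CSVs) or ``simulate``
    (a generator configuration) must be set.
    """

    output_dir: str | Path
    index_date: str | object = "2020-02-01"
    input_dir: str | Path | None = None
    simulate: synthetic.GeneratorConfig | None = None
    size_threshold: int = 10
    number_threshold: int = 10
    min_age: int = 65
    min_other_members: int = 3
    codelist: str = "primis"
    window: str = "ever"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ConfigurationError("exactly one of input_dir or simulate must be set")
        for name in ("size_threshold", "number_threshold", "min_age", "min_other_members"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "simulate" in data and data["simulate"] is not None:
            block = dict(data["simulate"])
            if "care_home_size_distribution" in block:
                block["care_home_size_distribution"] = {
                    int(k): float(v) for k, v in block["care_home_size_distribution"].items()
                }
            if "index_date" in block:
                block["index_date"] = as_timestamp(block["index_date"]).date()
            if "corruption_kinds" in block:
                block["corruption_kinds"] = tuple(block["corruption_kinds"])
            data["simulate"] = synthetic.GeneratorConfig(**block)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["output_dir"] = str(self.output_dir)
        out["input_dir"] = None if self.input_dir is None else str(self.input_dir)
        out["index_date"] = str(as_timestamp(self.index_date).date())
        if self.simulate is not None:
            out["simulate"] = self.simulate.to_dict()
        return out


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> Path:
    """simulate/load -> classify (three methods) -> compare -> write artifacts.

    Deterministic given the seed: re-running the same configuration produces
    byte-identical outputs. Returns the artifact directory.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    index_date = as_timestamp(config.index_date)

    if config.simulate is not None:
        generator_config = config.simulate
        if config.seed is not None:
            generator_config = dataclasses.replace(generator_config, seed=config.seed)
        data = synthetic.simulate(generator_config)
        tables = data.tables()
        write_tables(tables, out_dir / "tables")
    else:
        tables = read_tables(config.input_dir)

    codelist = rc.builtin_codelist(config.codelist)
    patients = tables["patients"]

    classification = al.classify_address_linkage(
        patients,
        tables["addresses"],
        tables["register"],
        index_date=index_date,
        size_threshold=config.size_threshold,
        number_threshold=config.number_threshold,
        min_age=config.min_age,
    )
    address_flags = al.flags_from_classification(classification)
    household_flags = rc.classify_household_rule(
        patients,
        tables["households"],
        index_date=index_date,
        min_age=config.min_age,
        min_other_members=config.min_other_members,
    )
    coded_flags = rc.classify_coded_events(
        tables["events"],
        codelist,
        index_date=index_date,
        window=config.window,
        patient_ids=patients["patient_id"],
    )

    population = cmp.restrict_population(patients, index_date, min_age=config.min_age)
    flags = cmp.assemble_method_flags(population, address_flags, household_flags, coded_flags)

    prevalence = cmp.prevalence_from_flags(flags)
    venn_summary = cmp.venn(flags)
    overlap = cmp.overlap_statistics(cmp.overlap_counts_from_flags(flags))
    characteristics = cmp.characteristics_table(flags, population, index_date=index_date)

    artifacts = {
        "classification": classification,
        "method_flags": flags,
        "prevalence": prevalence,
        "venn": venn_summary.to_frame(),
        "overlap": pd.DataFrame(
            [{"statistic": k, "value": v} for k, v in overlap.items()]
        ),
        "characteristics": characteristics.reset_index(),
    }
    write_tables(artifacts, out_dir)

    quality = rc.household_data_quality(patients)
    quality["n_population_65plus"] = int(len(population))
    scores = {}
    if "ground_truth" in tables:
        truth = tables["ground_truth"]
        for method, series in (
            ("address_linkage", address_flags),
            ("household_rule", household_flags),
            ("coded_events", coded_flags),
        ):
            scores[method] = synthetic.score_against_truth(series, truth)
        _atomic_write_text(json.dumps(scores, indent=2, sort_keys=True), out_dir / "scores.json")

    _atomic_write_text(
        json.dumps(quality, indent=2, sort_keys=True), out_dir / "data_quality.json"
    )
    manifest_config = config.to_dict()
    manifest_config.pop("output_dir", None)  # the manifest lives there already
    manifest = {
        "config": manifest_config,
        "versions": {
            "carehomelink": _package_version(),
            "pandas": pd.__version__,
        },
    }
    _atomic_write_text(json.dumps(manifest, indent=2, sort_keys=True), out_dir / "manifest.json")
    return out_dir


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("carehomelink")
    except PackageNotFoundError:
        return "unknown"
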