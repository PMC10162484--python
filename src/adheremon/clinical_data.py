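"""Common data model for clinical data, with a CSV reference connector.

Heterogeneous hospital EHR systems are integrated by converting their data
into one common tabular model that the adherence evaluator understands; the
reference serialization here is a directory of six CSV files (persons,
encounters, conditions, drug administrations, observations, procedures),
each row coded with standard terminologies.  Site-specific ETL connectors
producing these tables are out of scope — any source that can emit the six
tables can feed the engine.

Conventions
-----------
- Timestamps are ISO 8601, timezone-naive; a date-only value means 00:00 of
  that day.
- All event intervals are half-open ``[start, end)``: an event ending at
  00:00 of day *d* does not cover day *d*.
- An absent ``end``/``abatement`` means the episode is still open and is
  treated as extending to the end of the evaluation window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import CohortValidationError, DataFormatError

logger = logging.getLogger(__name__)

#: Terminology systems accepted in event tables.
_SYSTEMS = {"ICD10", "SNOMED", "ATC", "LOINC", "UCUM"}

#: table name -> (column, role) pairs; roles drive parsing and validation.
#: roles: str, int, float?, str?, dt (required datetime), dt? (optional)
TABLE_SCHEMAS: dict[str, list[tuple[str, str]]] = {
    "persons": [("person_id", "str"), ("birth_year", "int"), ("sex", "str?")],
    "encounters": [
        ("person_id", "str"),
        ("ward_type", "str"),
        ("start", "dt"),
        ("end", "dt?"),
    ],
    "conditions": [
        ("person_id", "str"),
        ("system", "str"),
        ("code", "str"),
        ("onset", "dt"),
        ("abatement", "dt?"),
    ],
    "drug_administrations": [
        ("person_id", "str"),
        ("system", "str"),
        ("code", "str"),
        ("dose_value", "float"),
        ("dose_unit", "str"),
        ("administered_at", "dt"),
    ],
    "observations": [
        ("person_id", "str"),
        ("system", "str"),
        ("code", "str"),
        ("value_num", "float?"),
        ("value_unit", "str?"),
        ("value_code", "str?"),
        ("observed_at", "dt"),
    ],
    "procedures": [
        ("person_id", "str"),
        ("system", "str"),
        ("code", "str"),
        ("start", "dt"),
        ("end", "dt?"),
    ],
}

EVENT_TABLES = tuple(name for name in TABLE_SCHEMAS if name != "persons")


class Finding(NamedTuple):
    """One data-quality finding: machine-readable, never an exception."""

    severity: str  # "error" | "warning"
    table: str
    row: int  # 0-based row index within the table; -1 for table-level findings
    message: str

    def __str__(self) -> str:
        where = f"{self.table}[{self.row}]" if self.row >= 0 else self.table
        return f"{self.severity}: {where}: {self.message}"


def empty_table(name: str) -> pd.DataFrame:
    """An empty table with the schema's columns and dtypes."""
    cols = {}
    for col, role in TABLE_SCHEMAS[name]:
        if role.startswith("dt"):
            cols[col] = pd.Series(dtype="datetime64[ns]")
        elif role.startswith("float"):
            cols[col] = pd.Series(dtype="float64")
        elif role == "int":
            cols[col] = pd.Series(dtype="int64")
        else:
            cols[col] = pd.Series(dtype="object")
    return pd.DataFrame(cols)


@dataclass
class CohortData:
    """The common-data-model bundle: one table per clinical domain."""

    persons: pd.DataFrame = field(default_factory=lambda: empty_table("persons"))
    encounters: pd.DataFrame = field(default_factory=lambda: empty_table("encounters"))
    conditions: pd.DataFrame = field(default_factory=lambda: empty_table("conditions"))
    drug_administrations: pd.DataFrame = field(
        default_factory=lambda: empty_table("drug_administrations")
    )
    observations: pd.DataFrame = field(default_factory=lambda: empty_table("observations"))
    procedures: pd.DataFrame = field(default_factory=lambda: empty_table("procedures"))

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def tables(self) -> Iterable[tuple[str, pd.DataFrame]]:
        for name in TABLE_SCHEMAS:
            yield name, self.table(name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortData):
            return NotImplemented
        for name, frame in self.tables():
            theirs = other.table(name)
            if not frame.reset_index(drop=True).equals(theirs.reset_index(drop=True)):
                return False
        return True


def _parse_column(series: pd.Series, role: str, table: str, col: str) -> pd.Series:
    """Parse one raw string column according to its schema role.

    Raises DataFormatError naming file and (1-based, header-inclusive) line
    of the first malformed value.
    """
    blank = series.isna() | (series.astype("string").str.strip() == "")
    optional = role.endswith("?")
    base = role.rstrip("?")
    if not optional and blank.any():
        line = int(blank.idxmax()) + 2
        raise DataFormatError(f"{table}.csv line {line}: column {col!r} must not be empty")
    if base == "str":
        out = series.astype("object").where(~blank, None)
        return out
    if base in ("int", "float"):
        parsed = pd.to_numeric(series.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise DataFormatError(
                f"{table}.csv line {line}: column {col!r} has non-numeric value "
                f"{series[bad.idxmax()]!r}"
            )
        if base == "int":
            if not blank.all() and not (parsed.dropna() % 1 == 0).all():
                raise DataFormatError(f"{table}.csv: column {col!r} must be integer")
            return parsed.astype("int64") if not blank.any() else parsed
        return parsed.astype("float64")
    if base == "dt":
        parsed = pd.to_datetime(series.where(~blank), errors="coerce", format="ISO8601")
        bad = parsed.isna() & ~blank
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise DataFormatError(
                f"{table}.csv line {line}: column {col!r} has invalid timestamp "
                f"{series[bad.idxmax()]!r}"
            )
        return parsed
    raise AssertionError(f"unknown role {role}")  # pragma: no cover


def _read_table(path: Path, name: str) -> pd.DataFrame:
    expected = [col for col, _ in TABLE_SCHEMAS[name]]
    try:
        raw = pd.read_csv(path, dtype="string", keep_default_na=False, na_values=[])
    except Exception as exc:
        raise DataFormatError(f"cannot read {path.name}: {exc}") from exc
    if list(raw.columns) != expected:
        raise DataFormatError(
            f"{path.name}: header must be {','.join(expected)}, got {','.join(raw.columns)}"
        )
    parsed = {}
    for col, role in TABLE_SCHEMAS[name]:
        series = raw[col].replace("", pd.NA)  # blank cells mean "absent"
        parsed[col] = _parse_column(series.reset_index(drop=True), role, name, col)
    frame = pd.DataFrame(parsed)
    if frame.empty:
        return empty_table(name)
    return frame


def load_cohort(directory_path: str | Path) -> CohortData:
    """Load and validate a cohort from a directory of the six CSV tables.

    Loading is strict: rows violating the data-model invariants are rejected
    with a :class:`~adheremon.errors.CohortValidationError` (no silent
    coercion), so every event in a returned :class:`CohortData` satisfies
    its invariants.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise DataFormatError(f"cohort directory not found: {directory}")
    frames = {}
    for name in TABLE_SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.is_file():
            raise DataFormatError(f"missing required file: {path.name}")
        frames[name] = _read_table(path, name)
        logger.info("loaded %s: %d rows", path.name, len(frames[name]))
    cohort = CohortData(**frames)
    errors = [f for f in validate_cohort(cohort) if f.severity == "error"]
    if errors:
        raise CohortValidationError(errors)
    return cohort


def validate_cohort(cohort: CohortData) -> list[Finding]:
    """Check the common-data-model invariants; return findings, never raise.

    Checks referential integrity (every event's person exists), interval
    sanity (start <= end), dose positivity, the one-of-value rule for
    observations, and terminology-system membership.
    """
    findings: list[Finding] = []
    persons = cohort.persons
    if persons["person_id"].duplicated().any():
        for idx in persons.index[persons["person_id"].duplicated()]:
            findings.append(
                Finding("error", "persons", int(idx), f"duplicate person_id {persons.at[idx, 'person_id']!r}")
            )
    known = set(persons["person_id"])
    for name in EVENT_TABLES:
        frame = cohort.table(name)
        if frame.empty:
            continue
        orphan = ~frame["person_id"].isin(known)
        for idx in frame.index[orphan]:
            findings.append(
                Finding("error", name, int(idx), f"unknown person_id {frame.at[idx, 'person_id']!r}")
            )
        if "system" in frame.columns:
            bad_sys = ~frame["system"].isin(_SYSTEMS)
            for idx in frame.index[bad_sys]:
                findings.append(
                    Finding("error", name, int(idx), f"unknown terminology system {frame.at[idx, 'system']!r}")
                )
    for name, start_col, end_col in (
        ("encounters", "start", "end"),
        ("conditions", "onset", "abatement"),
        ("procedures", "start", "end"),
    ):
        frame = cohort.table(name)
        if frame.empty:
            continue
        bad = frame[end_col].notna() & (frame[end_col] < frame[start_col])
        for idx in frame.index[bad]:
            findings.append(
                Finding("error", name, int(idx), f"{end_col} before {start_col}")
            )
    drugs = cohort.drug_administrations
    if not drugs.empty:
        bad = ~(drugs["dose_value"] > 0)
        for idx in drugs.index[bad]:
            findings.append(
                Finding("error", "drug_administrations", int(idx), f"dose_value must be > 0, got {drugs.at[idx, 'dose_value']}")
            )
    obs = cohort.observations
    if not obs.empty:
        has_num = obs["value_num"].notna()
        has_code = obs["value_code"].notna()
        bad = has_num == has_code  # neither or both
        for idx in obs.index[bad]:
            findings.append(
                Finding("error", "observations", int(idx), "exactly one of value_num/value_code must be present")
            )
        missing_unit = has_num & obs["value_unit"].isna()
        for idx in obs.index[missing_unit]:
            findings.append(
                Finding("warning", "observations", int(idx), "numeric value without unit")
            )
    return findings


def _format_cell(value, role: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NaT:
        return ""
    if role.startswith("dt"):
        ts = pd.Timestamp(value)
        return ts.isoformat()
    if role.startswith("float"):
        return repr(float(value))
    return str(value)


def write_cohort(cohort: CohortData, directory: str | Path) -> list[Path]:
    """Write the six CSV tables of ``cohort`` into ``directory``.

    Inverse of :func:`load_cohort`: ``load_cohort(write_cohort(c)) == c``,
    and the byte content is deterministic for a given cohort.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in cohort.tables():
        roles = dict(TABLE_SCHEMAS[name])
        out = pd.DataFrame(
            {col: [_format_cell(v, roles[col]) for v in frame[col]] for col in frame.columns}
        )
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written
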