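"""Shared test helpers: compact cohort construction from row tuples."""

from __future__ import annotations

import datetime as dt

import pandas as pd

from adheremon.clinical_data import TABLE_SCHEMAS, CohortData, empty_table


def _coerce(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    for col, role in TABLE_SCHEMAS[name]:
        if role.startswith("dt"):
            frame[col] = pd.to_datetime(frame[col])
        elif role.startswith("float"):
            frame[col] = pd.to_numeric(frame[col]).astype("float64")
        elif role == "int":
            frame[col] = frame[col].astype("int64")
    return frame


def make_cohort(
    persons=(),
    encounters=(),
    conditions=(),
    drugs=(),
    observations=(),
    procedures=(),
) -> CohortData:
    """Build a CohortData from row tuples in schema column order.

    ``persons`` entries may be bare person_id strings (birth year 1970, no sex).
    """
    persons = [(p, 1970, None) if isinstance(p, str) else p for p in persons]
    tables = {
        "persons": persons,
        "encounters": encounters,
        "conditions": conditions,
        "drug_administrations": drugs,
        "observations": observations,
        "procedures": procedures,
    }
    frames = {}
    for name, rows in tables.items():
        if not rows:
            frames[name] = empty_table(name)
        else:
            cols = [col for col, _ in TABLE_SCHEMAS[name]]
            frames[name] = _coerce(pd.DataFrame(list(rows), columns=cols), name)
    return CohortData(**frames)


def d(day: int, hour: int = 0, base: dt.date = dt.date(2020, 3, 1)) -> dt.datetime:
    """Datetime at ``hour`` o'clock of day number ``day`` (1-based) from a base date."""
    return dt.datetime.combine(base + dt.timedelta(days=day - 1), dt.time(hour))


def day(n: int, base: dt.date = dt.date(2020, 3, 1)) -> dt.date:
    """Calendar date of day number ``n`` (1-based) from a base date."""
    return base + dt.timedelta(days=n - 1)
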