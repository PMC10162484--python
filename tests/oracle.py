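"""Independent brute-force reference evaluator.

Evaluates a recommendation directly from the raw criterion trees and raw
cohort rows, per (patient, day, leaf), with no rule compilation, no
precomputed day sets, and its own unit table.  Dosage criteria are checked
by literal enumeration of every candidate course start.  Deliberately slow
and simple: this is the ground truth the engine is compared against.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from adheremon.model import Criterion, Recommendation
from adheremon.terminology import CodeMap, resolve

_ONE_DAY = dt.timedelta(days=1)

# independent conversion table (to mg / to hours / to percent)
_TO_BASE = {"ug": 0.001, "mg": 1.0, "g": 1000.0, "%": 1.0, "h": 1.0, "d": 24.0}
_GROUP = {"ug": "m", "mg": "m", "g": "m", "%": "p", "h": "t", "d": "t"}


def conv(value: float, from_u: str, to_u: str) -> float:
    assert _GROUP[from_u] == _GROUP[to_u], f"incomparable {from_u}/{to_u}"
    return value * _TO_BASE[from_u] / _TO_BASE[to_u]


class _PersonRows:
    """One person's rows from every table, as plain python tuples."""

    def __init__(self, cohort, pid: str):
        self.tables = {}
        for name in (
            "encounters",
            "conditions",
            "drug_administrations",
            "observations",
            "procedures",
        ):
            frame = getattr(cohort, name)
            frame = frame[frame["person_id"] == pid]
            self.tables[name] = list(frame.itertuples(index=False))


def _covers(start, end, day: dt.date) -> bool:
    """Half-open [start, end) interval intersects the day; open end covers."""
    day_start = dt.datetime.combine(day, dt.time(0))
    day_end = day_start + _ONE_DAY
    s = pd.Timestamp(start).to_pydatetime()
    if s >= day_end:
        return False
    if end is None or pd.isna(end):
        return True
    return pd.Timestamp(end).to_pydatetime() > day_start


def _local_keys(crit: Criterion, codemap: CodeMap) -> set[tuple[str, str]]:
    return {c.key() for c in resolve(codemap, crit.concept)}


def leaf_true(
    crit: Criterion,
    codemap: CodeMap,
    cohort_or_rows,
    person_id: str,
    day: dt.date,
    dose_tolerance: float = 0.10,
) -> bool:
    """Un-negated-then-negated truth of one criterion leaf."""
    rows = (
        cohort_or_rows
        if isinstance(cohort_or_rows, _PersonRows)
        else _PersonRows(cohort_or_rows, person_id)
    )
    base = _leaf_base(crit, codemap, rows, day, dose_tolerance)
    return (not base) if crit.negated else base


def _leaf_base(crit, codemap, rows: _PersonRows, day, tol) -> bool:
    keys = _local_keys(crit, codemap)
    if crit.kind == "condition":
        return any(
            (r.system, r.code) in keys and _covers(r.onset, r.abatement, day)
            for r in rows.tables["conditions"]
        )
    if crit.kind == "procedure_active":
        return any(
            (r.system, r.code) in keys and _covers(r.start, r.end, day)
            for r in rows.tables["procedures"]
        )
    if crit.kind == "episode_attribute":
        wards = {c for _, c in keys}
        return any(
            r.ward_type in wards and _covers(r.start, r.end, day)
            for r in rows.tables["encounters"]
        )
    if crit.kind == "drug_administration":
        matching = [
            r for r in rows.tables["drug_administrations"] if (r.system, r.code) in keys
        ]
        if crit.dosage is None:
            return any(pd.Timestamp(r.administered_at).date() == day for r in matching)
        return _dosage_true(crit, matching, day, tol)
    if crit.kind == "observation":
        day_end = dt.datetime.combine(day, dt.time(0)) + _ONE_DAY
        eligible = [
            (i, r)
            for i, r in enumerate(rows.tables["observations"])
            if (r.system, r.code) in keys
            and pd.Timestamp(r.observed_at).to_pydatetime() < day_end
        ]
        if not eligible:
            return False
        _, last = max(eligible, key=lambda t: (pd.Timestamp(t[1].observed_at), t[0]))
        if pd.isna(last.value_num):
            return False  # code-valued result, numeric comparator
        value = conv(float(last.value_num), str(last.value_unit), crit.threshold.unit.code)
        t = crit.threshold.value
        return {
            "<": value < t,
            "<=": value <= t,
            "=": abs(value - t) <= 1e-9 * max(abs(value), abs(t), 1e-12),
            ">=": value >= t,
            ">": value > t,
        }[crit.comparator]
    raise AssertionError(crit.kind)


def _dosage_true(crit: Criterion, matching: list, day: dt.date, tol: float) -> bool:
    """Enumerate every candidate course start and test the course literally."""
    spec = crit.dosage
    per_day: dict[dt.date, list[float]] = {}
    for r in matching:
        per_day.setdefault(pd.Timestamp(r.administered_at).date(), []).append(
            conv(float(r.dose_value), str(r.dose_unit), spec.dose.unit.code)
        )
    admin_days = set(per_day)
    expected = spec.dose.value * spec.frequency_per_day

    def qualifying(d: dt.date) -> bool:
        doses = per_day.get(d, [])
        return (
            len(doses) == spec.frequency_per_day
            and abs(sum(doses) - expected) <= tol * expected
        )

    starts = [s for s in admin_days if s - _ONE_DAY not in admin_days]
    for s in starts:
        if s > day:
            continue
        if spec.bounded and (day - s).days >= spec.duration_days:
            continue  # a completed course does not cover later days
        span = [(s + dt.timedelta(days=k)) for k in range((day - s).days + 1)]
        if all(qualifying(d) for d in span):
            return True
    return False


def node_true(node, codemap, cohort_or_rows, pid, day, tol=0.10) -> bool:
    if isinstance(node, Criterion):
        return leaf_true(node, codemap, cohort_or_rows, pid, day, tol)
    values = [node_true(m, codemap, cohort_or_rows, pid, day, tol) for m in node.members]
    value = all(values) if node.operator == "ALL_OF" else any(values)
    return (not value) if node.negated else value


def _admitted(rows: _PersonRows, day: dt.date) -> bool:
    return any(_covers(r.start, r.end, day) for r in rows.tables["encounters"])


def evaluate_brute(
    rec: Recommendation, codemap: CodeMap, cohort, window, dose_tolerance: float = 0.10
) -> list[tuple]:
    """Full-cohort brute-force evaluation; rows mirror DayResult fields."""
    out = []
    for pid in cohort.persons["person_id"]:
        rows = _PersonRows(cohort, pid)
        for day in window.days():
            pop = _admitted(rows, day) and node_true(
                rec.population, codemap, rows, pid, day, dose_tolerance
            )
            interv = node_true(rec.intervention, codemap, rows, pid, day, dose_tolerance)
            out.append((pid, day, pop, interv, pop and interv))
    return out
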