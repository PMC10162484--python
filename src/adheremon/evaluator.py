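"""The adherence evaluation engine.

A :class:`~adheremon.model.Recommendation` is *compiled* into an executable
event-condition-action plan: the population and intervention criterion trees
are mirrored into rule trees whose leaves are bound to the local data codes
obtained from the concept map.  The plan is then *executed* against a
:class:`~adheremon.clinical_data.CohortData` at day granularity, producing
for every patient and every day of an evaluation window three truth values:

- ``population_applicable`` — the patient has an active encounter that day
  and satisfies the population criterion tree (the recommendation applies);
- ``intervention_fulfilled`` — the patient satisfies the intervention tree;
- ``adherent`` — both of the above.

Evaluation is closed-world: absence of a matching record makes a criterion
false (before negation).  There is no randomness anywhere in evaluation;
identical inputs yield identical outputs.

Dosage semantics
----------------
A drug criterion with a :class:`~adheremon.model.DosageSpec` is fulfilled on
a day iff a conformant course covers that day.  A *course start* is an
administration day not preceded by an administration on the previous day
(i.e. the first day of an administration run — a new course may begin after
an interruption).  A course starting on day *s* covers day *d* iff
``s <= d < s + duration_days`` and every day in ``[s, d]`` has exactly
``frequency_per_day`` matching administrations whose daily total dose is
within a relative tolerance (default 10%) of the recommended daily dose.
Days of a run beyond the recommended duration are not covered (an over-long
course is non-conformant on its tail), and days mid-course count as
fulfilled without lookahead ("ongoing-adherent").
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Union

import numpy as np
import pandas as pd

from .clinical_data import CohortData
from .errors import EvaluationError, TerminologyError, UnitError
from .model import Criterion, CriterionCombination, Quantity, Recommendation
from .terminology import CodeMap, identity_codemap, resolve
from .units import convert

#: Default relative tolerance on the daily total dose.
DEFAULT_DOSE_TOLERANCE = 0.10

_ONE_DAY = _dt.timedelta(days=1)


@dataclass(frozen=True)
class EvaluationWindow:
    """An inclusive range of calendar days evaluated at day granularity."""

    start_date: _dt.date
    end_date: _dt.date

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("end_date must not precede start_date")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def days(self) -> list[_dt.date]:
        return [self.start_date + _dt.timedelta(days=i) for i in range(self.n_days)]

    def __contains__(self, day: _dt.date) -> bool:
        return self.start_date <= day <= self.end_date


@dataclass(frozen=True)
class CompiledCriterion:
    """A criterion leaf bound to the local codes that realize its concept."""

    path: str
    criterion: Criterion
    local_keys: tuple[tuple[str, str], ...]  # (system, code) pairs, >= 1


@dataclass(frozen=True)
class CompiledCombination:
    """A compiled boolean node mirroring a CriterionCombination."""

    path: str
    operator: str
    negated: bool
    members: tuple[Union["CompiledCombination", CompiledCriterion], ...]


CompiledNode = Union[CompiledCombination, CompiledCriterion]


@dataclass(frozen=True)
class ExecutablePlan:
    """The executable form of one recommendation version.

    A pure data object: compiling touches no patient data, and compiling the
    same recommendation twice yields equal plans.
    """

    recommendation_id: str
    version: str
    population: CompiledCombination
    intervention: CompiledCombination
    dose_tolerance: float = DEFAULT_DOSE_TOLERANCE

    def leaves(self) -> Iterator[CompiledCriterion]:
        yield from _iter_leaves(self.population)
        yield from _iter_leaves(self.intervention)


def _iter_leaves(node: CompiledNode) -> Iterator[CompiledCriterion]:
    if isinstance(node, CompiledCriterion):
        yield node
    else:
        for member in node.members:
            yield from _iter_leaves(member)


class DayResult(NamedTuple):
    """Per patient-day verdicts; ``adherent == population_applicable and
    intervention_fulfilled`` by construction."""

    person_id: str
    date: _dt.date
    population_applicable: bool
    intervention_fulfilled: bool
    adherent: bool


@dataclass
class EvaluationResult:
    """Output bundle of :func:`evaluate_cohort`."""

    series: pd.DataFrame  # date, n_applicable, n_adherent, fraction
    day_results: pd.DataFrame  # person_id, date, population_applicable, ...
    leaf_results: Optional[pd.DataFrame] = None  # person_id, date, criterion_path, result


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

def _compile_node(
    node: Union[Criterion, CriterionCombination], codemap: CodeMap, path: str
) -> CompiledNode:
    if isinstance(node, Criterion):
        try:
            local = resolve(codemap, node.concept)
        except TerminologyError as exc:
            raise TerminologyError(f"{path}: {exc}") from exc
        return CompiledCriterion(
            path=path,
            criterion=node,
            local_keys=tuple(c.key() for c in local),
        )
    members = tuple(
        _compile_node(member, codemap, f"{path}/members/{i}")
        for i, member in enumerate(node.members)
    )
    return CompiledCombination(
        path=path, operator=node.operator, negated=node.negated, members=members
    )


def compile(
    rec: Recommendation,
    codemap: Optional[CodeMap] = None,
    dose_tolerance: float = DEFAULT_DOSE_TOLERANCE,
) -> ExecutablePlan:
    """Compile a recommendation into an executable plan.

    Every criterion concept is resolved through ``codemap`` (default: a
    lenient identity map); in strict maps an unresolvable concept raises
    :class:`~adheremon.errors.TerminologyError` naming the criterion path.
    """
    if codemap is None:
        codemap = identity_codemap()
    return ExecutablePlan(
        recommendation_id=rec.id,
        version=rec.version,
        population=_compile_node(rec.population, codemap, "/population"),
        intervention=_compile_node(rec.intervention, codemap, "/intervention"),
        dose_tolerance=float(dose_tolerance),
    )


# ---------------------------------------------------------------------------
# Per-person leaf preparation
# ---------------------------------------------------------------------------

def _interval_days(
    start: _dt.datetime, end: Optional[_dt.datetime], window: EvaluationWindow
) -> Iterator[_dt.date]:
    """Days of ``window`` covered by the half-open interval [start, end).

    An open end (None) extends to the end of the window.
    """
    first = max(start.date(), window.start_date)
    if end is None:
        last = window.end_date
    else:
        # interval covers day d iff end > 00:00 of d
        last = end.date() if end.time() != _dt.time(0) else end.date() - _ONE_DAY
        last = min(last, window.end_date)
    day = first
    while day <= last:
        yield day
        day += _ONE_DAY


_COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
    "=": lambda a, b: math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-12),
}


def _prepare_leaf_days(
    leaf: CompiledCriterion,
    rows: pd.DataFrame,
    window: EvaluationWindow,
    dose_tolerance: float,
) -> set[_dt.date]:
    """The set of window days on which the (un-negated) leaf is true.

    ``rows`` are the person's concept-matching rows of the relevant table.
    """
    crit = leaf.criterion
    days: set[_dt.date] = set()
    if crit.kind in ("condition", "procedure_active", "episode_attribute"):
        start_col = "onset" if crit.kind == "condition" else "start"
        end_col = "abatement" if crit.kind == "condition" else "end"
        for start, end in zip(rows[start_col], rows[end_col]):
            s = pd.Timestamp(start).to_pydatetime()
            e = None if pd.isna(end) else pd.Timestamp(end).to_pydatetime()
            days.update(_interval_days(s, e, window))
        return days

    if crit.kind == "drug_administration":
        if crit.dosage is None:
            for ts in rows["administered_at"]:
                day = pd.Timestamp(ts).date()
                if day in window:
                    days.add(day)
            return days
        return _dosage_days(crit, rows, window, dose_tolerance)

    if crit.kind == "observation":
        return _observation_days(crit, rows, window)

    raise AssertionError(f"unknown criterion kind {crit.kind}")  # pragma: no cover


def _dosage_days(
    crit: Criterion, rows: pd.DataFrame, window: EvaluationWindow, tolerance: float
) -> set[_dt.date]:
    spec = crit.dosage
    target_unit = spec.dose.unit.code
    expected_daily = spec.dose.value * spec.frequency_per_day
    bounded = spec.bounded
    duration = spec.duration_days if bounded else None

    # daily administration count and total dose in the recommended unit
    per_day: dict[_dt.date, list[float]] = {}
    for ts, value, unit in zip(rows["administered_at"], rows["dose_value"], rows["dose_unit"]):
        day = pd.Timestamp(ts).date()
        per_day.setdefault(day, []).append(convert(float(value), str(unit), target_unit))

    def qualifying(day: _dt.date) -> bool:
        doses = per_day[day]
        if len(doses) != spec.frequency_per_day:
            return False
        return abs(sum(doses) - expected_daily) <= tolerance * expected_daily

    fulfilled: set[_dt.date] = set()
    prev: Optional[_dt.date] = None
    run_start: Optional[_dt.date] = None
    run_ok = True
    for day in sorted(per_day):
        if prev is None or (day - prev).days > 1:
            run_start = day  # the only candidate course start inside a run
            run_ok = True
        run_ok = run_ok and qualifying(day)
        within_duration = duration is None or (day - run_start).days < duration
        if run_ok and within_duration and day in window:
            fulfilled.add(day)
        prev = day
    return fulfilled


def _observation_days(
    crit: Criterion, rows: pd.DataFrame, window: EvaluationWindow
) -> set[_dt.date]:
    threshold: Quantity = crit.threshold
    cmp = _COMPARATORS[crit.comparator]
    obs = sorted(
        zip(rows["observed_at"], rows["value_num"], rows["value_unit"], rows["value_code"]),
        key=lambda r: pd.Timestamp(r[0]),
    )
    days: set[_dt.date] = set()
    idx = 0
    last = None
    for day in window.days():
        day_end = _dt.datetime.combine(day + _ONE_DAY, _dt.time(0))
        while idx < len(obs) and pd.Timestamp(obs[idx][0]).to_pydatetime() < day_end:
            last = obs[idx]
            idx += 1
        if last is None:
            continue
        _, value_num, value_unit, value_code = last
        if value_num is None or (isinstance(value_num, float) and np.isnan(value_num)):
            continue  # code-valued result cannot satisfy a numeric comparator
        if value_unit is None or (isinstance(value_unit, float) and pd.isna(value_unit)):
            raise UnitError(
                f"observation value for {crit.concept} has no unit; cannot compare "
                f"against threshold unit {threshold.unit.code!r}"
            )
        value = convert(float(value_num), str(value_unit), threshold.unit.code)
        if cmp(value, threshold.value):
            days.add(day)
    return days


_TABLE_FOR_KIND = {
    "condition": "conditions",
    "drug_administration": "drug_administrations",
    "observation": "observations",
    "procedure_active": "procedures",
    "episode_attribute": "encounters",
}


def _matching_rows(leaf: CompiledCriterion, table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        return table
    if leaf.criterion.kind == "episode_attribute":
        # encounters carry a bare ward-type code, no terminology system
        codes = {code for _, code in leaf.local_keys}
        return table[table["ward_type"].isin(codes)]
    keys = table["system"].astype(str) + "|" + table["code"].astype(str)
    wanted = {f"{system}|{code}" for system, code in leaf.local_keys}
    return table[keys.isin(wanted)]


class _PlanIndex:
    """Per-(plan, cohort, window) evaluation index.

    For every leaf and person, precomputes the set of window days on which
    the un-negated leaf is true, plus the admitted-day set per person.
    """

    def __init__(
        self, plan: ExecutablePlan, cohort: CohortData, window: EvaluationWindow
    ) -> None:
        self.window = window
        self.person_ids: list[str] = list(cohort.persons["person_id"])
        known = set(self.person_ids)

        self.admitted: dict[str, set[_dt.date]] = {pid: set() for pid in known}
        enc = cohort.encounters
        for pid, start, end in zip(enc["person_id"], enc["start"], enc["end"]):
            if pid not in known:
                continue
            s = pd.Timestamp(start).to_pydatetime()
            e = None if pd.isna(end) else pd.Timestamp(end).to_pydatetime()
            self.admitted[pid].update(_interval_days(s, e, window))

        self.leaf_days: dict[str, dict[str, set[_dt.date]]] = {}
        for leaf in plan.leaves():
            table = cohort.table(_TABLE_FOR_KIND[leaf.criterion.kind])
            matching = _matching_rows(leaf, table)
            per_person: dict[str, set[_dt.date]] = {}
            if not matching.empty:
                for pid, rows in matching.groupby("person_id", sort=False):
                    per_person[str(pid)] = _prepare_leaf_days(
                        leaf, rows, window, plan.dose_tolerance
                    )
            self.leaf_days[leaf.path] = per_person

    def leaf_truth(self, leaf: CompiledCriterion, person_id: str, day: _dt.date) -> bool:
        base = day in self.leaf_days[leaf.path].get(person_id, ())
        return (not base) if leaf.criterion.negated else base

    def node_truth(self, node: CompiledNode, person_id: str, day: _dt.date) -> bool:
        if isinstance(node, CompiledCriterion):
            return self.leaf_truth(node, person_id, day)
        if node.operator == "ALL_OF":
            value = all(self.node_truth(m, person_id, day) for m in node.members)
        else:
            value = any(self.node_truth(m, person_id, day) for m in node.members)
        return (not value) if node.negated else value


# ---------------------------------------------------------------------------
# Public evaluation operations
# ---------------------------------------------------------------------------

def _as_compiled_leaf(leaf: Union[CompiledCriterion, Criterion]) -> CompiledCriterion:
    if isinstance(leaf, Criterion):
        return CompiledCriterion(path="/", criterion=leaf, local_keys=(leaf.concept.key(),))
    return leaf


def _require_person(cohort: CohortData, person_id: str) -> None:
    if person_id not in set(cohort.persons["person_id"]):
        raise EvaluationError(f"unknown person_id {person_id!r}")


def evaluate_criterion(
    leaf: Union[CompiledCriterion, Criterion],
    cohort: CohortData,
    person_id: str,
    date: _dt.date,
    dose_tolerance: float = DEFAULT_DOSE_TOLERANCE,
) -> bool:
    """Evaluate one criterion for one patient on one day (closed-world)."""
    compiled = _as_compiled_leaf(leaf)
    _require_person(cohort, person_id)
    window = EvaluationWindow(date, date)
    table = cohort.table(_TABLE_FOR_KIND[compiled.criterion.kind])
    rows = _matching_rows(compiled, table)
    rows = rows[rows["person_id"] == person_id]
    if compiled.criterion.kind == "drug_administration" and compiled.criterion.dosage is not None:
        # course history before the query date matters; widen the preparation
        # window backwards so runs starting earlier are seen
        if not rows.empty:
            earliest = min(pd.Timestamp(ts).date() for ts in rows["administered_at"])
            window = EvaluationWindow(min(earliest, date), date)
    base_days = _prepare_leaf_days(compiled, rows, window, dose_tolerance)
    base = date in base_days
    return (not base) if compiled.criterion.negated else base


def evaluate_dosage(
    leaf: Union[CompiledCriterion, Criterion],
    cohort: CohortData,
    person_id: str,
    date: _dt.date,
    dose_tolerance: float = DEFAULT_DOSE_TOLERANCE,
) -> bool:
    """Evaluate a drug criterion with a dosing schedule (see module docstring
    for the course semantics)."""
    compiled = _as_compiled_leaf(leaf)
    if compiled.criterion.dosage is None:
        raise ValueError("evaluate_dosage requires a criterion with a DosageSpec")
    return evaluate_criterion(compiled, cohort, person_id, date, dose_tolerance)


def evaluate_combination(
    node: Union[CompiledCombination, CriterionCombination],
    cohort: CohortData,
    person_id: str,
    date: _dt.date,
    dose_tolerance: float = DEFAULT_DOSE_TOLERANCE,
) -> bool:
    """Evaluate a boolean criterion grouping for one patient on one day."""
    if isinstance(node, CriterionCombination):
        compiled = _compile_node(node, identity_codemap(), "/")
        return evaluate_combination(compiled, cohort, person_id, date, dose_tolerance)
    if isinstance(node, CompiledCriterion):
        return evaluate_criterion(node, cohort, person_id, date, dose_tolerance)
    results = (
        evaluate_combination(m, cohort, person_id, date, dose_tolerance)
        for m in node.members
    )
    value = all(results) if node.operator == "ALL_OF" else any(results)
    return (not value) if node.negated else value


def evaluate_patient(
    plan: ExecutablePlan,
    cohort: CohortData,
    person_id: str,
    window: EvaluationWindow,
) -> list[DayResult]:
    """Evaluate one patient over every day of the window.

    A day's ``population_applicable`` additionally requires an active
    encounter covering that day: a recommendation does not apply to patients
    who are not admitted.
    """
    _require_person(cohort, person_id)
    index = _PlanIndex(plan, cohort, window)
    return _patient_days(plan, index, person_id)


def _patient_days(
    plan: ExecutablePlan, index: _PlanIndex, person_id: str
) -> list[DayResult]:
    results = []
    admitted = index.admitted.get(person_id, set())
    for day in index.window.days():
        pop = day in admitted and index.node_truth(plan.population, person_id, day)
        interv = index.node_truth(plan.intervention, person_id, day)
        results.append(DayResult(person_id, day, pop, interv, pop and interv))
    return results


def evaluate_cohort(
    plan: ExecutablePlan,
    cohort: CohortData,
    window: EvaluationWindow,
    collect_leaves: bool = False,
) -> EvaluationResult:
    """Evaluate every patient in the cohort over the window and aggregate
    per-day applicable/adherent counts.

    The per-day ``fraction`` is ``n_adherent / n_applicable`` and NaN
    (serialized as null) on days with no applicable patient.  With
    ``collect_leaves=True`` every leaf verdict (plus the ``/admitted``
    encounter gate) is recorded for raw-data review and auditability.
    """
    index = _PlanIndex(plan, cohort, window)
    days = window.days()
    n_applicable = {d: 0 for d in days}
    n_adherent = {d: 0 for d in days}
    all_results: list[DayResult] = []
    leaf_rows: list[tuple[str, _dt.date, str, bool]] = []
    leaves = list(plan.leaves())

    for person_id in index.person_ids:
        day_results = _patient_days(plan, index, person_id)
        all_results.extend(day_results)
        for res in day_results:
            if res.population_applicable:
                n_applicable[res.date] += 1
            if res.adherent:
                n_adherent[res.date] += 1
        if collect_leaves:
            admitted = index.admitted.get(person_id, set())
            for day in days:
                leaf_rows.append((person_id, day, "/admitted", day in admitted))
                for leaf in leaves:
                    leaf_rows.append(
                        (person_id, day, leaf.path, index.leaf_truth(leaf, person_id, day))
                    )

    series = pd.DataFrame(
        {
            "date": days,
            "n_applicable": [n_applicable[d] for d in days],
            "n_adherent": [n_adherent[d] for d in days],
        }
    )
    series["fraction"] = np.where(
        series["n_applicable"] > 0,
        series["n_adherent"] / series["n_applicable"].replace(0, np.nan),
        np.nan,
    )
    day_frame = pd.DataFrame(all_results, columns=DayResult._fields)
    leaf_frame = None
    if collect_leaves:
        leaf_frame = pd.DataFrame(
            leaf_rows, columns=["person_id", "date", "criterion_path", "result"]
        )
    return EvaluationResult(series=series, day_results=day_frame, leaf_results=leaf_frame)
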