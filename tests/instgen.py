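"""Seeded random instance generator for engine-vs-oracle comparisons.

Generates small random cohorts (up to 20 patients over up to 30 days) and
random recommendation criterion trees (depth up to 3) drawing from a small
shared concept vocabulary, so criteria sometimes match data and sometimes
do not.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

from adheremon.evaluator import EvaluationWindow
from adheremon.model import (
    ConceptCode,
    Criterion,
    CriterionCombination,
    DosageSpec,
    Quantity,
    Recommendation,
)

from helpers import make_cohort

BASE = dt.date(2020, 3, 1)

CONDITIONS = [ConceptCode(system="ICD10", code=c) for c in ("U07.1", "J96.0", "N17.9")]
PROCEDURES = [ConceptCode(system="SNOMED", code=c) for c in ("57485005", "40617009")]
DRUGS = [ConceptCode(system="ATC", code=c) for c in ("H02AB02", "B01AB01")]
OBSERVATIONS = [ConceptCode(system="LOINC", code="59408-5")]
WARDS = ["ICU", "NORMAL"]
PCT = ConceptCode(system="UCUM", code="%")
MG = ConceptCode(system="UCUM", code="mg")


def _ts(day_index: int, hour: int) -> dt.datetime:
    return dt.datetime.combine(BASE + dt.timedelta(days=day_index), dt.time(hour))


def random_criterion(rng: np.random.Generator) -> Criterion:
    kind = rng.choice(
        ["condition", "drug_administration", "observation", "procedure_active", "episode_attribute"]
    )
    negated = bool(rng.random() < 0.25)
    if kind == "condition":
        return Criterion(kind=kind, concept=CONDITIONS[rng.integers(len(CONDITIONS))], negated=negated)
    if kind == "procedure_active":
        return Criterion(kind=kind, concept=PROCEDURES[rng.integers(len(PROCEDURES))], negated=negated)
    if kind == "episode_attribute":
        ward = WARDS[rng.integers(len(WARDS))]
        return Criterion(kind=kind, concept=ConceptCode(system="SNOMED", code=ward), negated=negated)
    if kind == "observation":
        return Criterion(
            kind=kind,
            concept=OBSERVATIONS[0],
            comparator=rng.choice(["<", "<=", "=", ">=", ">"]),
            threshold=Quantity(value=float(rng.integers(85, 99)), unit=PCT),
            negated=negated,
        )
    dosage = None
    if rng.random() < 0.5:
        dosage = DosageSpec(
            dose=Quantity(value=1.0, unit=MG),
            frequency_per_day=int(rng.integers(1, 3)),
            duration_days="unbounded" if rng.random() < 0.3 else int(rng.integers(2, 6)),
        )
    return Criterion(
        kind="drug_administration",
        concept=DRUGS[rng.integers(len(DRUGS))],
        dosage=dosage,
        negated=negated,
    )


def random_tree(rng: np.random.Generator, depth: int = 3) -> CriterionCombination:
    members = []
    for _ in range(int(rng.integers(1, 4))):
        if depth > 1 and rng.random() < 0.35:
            members.append(random_tree(rng, depth - 1))
        else:
            members.append(random_criterion(rng))
    return CriterionCombination(
        operator=rng.choice(["ALL_OF", "ANY_OF"]),
        members=tuple(members),
        negated=bool(rng.random() < 0.2),
    )


def random_recommendation(rng: np.random.Generator) -> Recommendation:
    return Recommendation(
        id="random-rec",
        title="randomly generated recommendation",
        version="1.0",
        valid_from=BASE,
        population=random_tree(rng),
        intervention=random_tree(rng),
    )


def random_cohort(rng: np.random.Generator, max_patients: int = 20, n_days: int = 30):
    """A random cohort over ``n_days`` days starting at BASE."""
    n = int(rng.integers(1, max_patients + 1))
    persons, encounters, conditions, drugs, observations, procedures = [], [], [], [], [], []
    for i in range(n):
        pid = f"R{i:03d}"
        persons.append((pid, int(rng.integers(1940, 2000)), None))
        for _ in range(int(rng.integers(0, 3))):
            s = int(rng.integers(0, n_days))
            length = int(rng.integers(1, 15))
            end = None if rng.random() < 0.15 else _ts(s + length, 0)
            encounters.append((pid, WARDS[rng.integers(2)], _ts(s, 0), end))
        for _ in range(int(rng.integers(0, 3))):
            c = CONDITIONS[rng.integers(len(CONDITIONS))]
            s = int(rng.integers(0, n_days))
            end = None if rng.random() < 0.3 else _ts(s + int(rng.integers(1, 12)), 0)
            conditions.append((pid, c.system, c.code, _ts(s, 8), end))
        for _ in range(int(rng.integers(0, 3))):
            p = PROCEDURES[rng.integers(len(PROCEDURES))]
            s = int(rng.integers(0, n_days))
            end = None if rng.random() < 0.3 else _ts(s + int(rng.integers(1, 12)), 0)
            procedures.append((pid, p.system, p.code, _ts(s, 8), end))
        # drug course: consecutive-ish days, occasionally gapped / double-dosed
        if rng.random() < 0.7:
            drug = DRUGS[rng.integers(len(DRUGS))]
            s = int(rng.integers(0, n_days - 2))
            for k in range(int(rng.integers(1, 9))):
                if rng.random() < 0.15:
                    continue  # gap
                day_index = s + k
                n_doses = 2 if rng.random() < 0.25 else 1
                for j in range(n_doses):
                    value, unit = (1.0, "mg") if rng.random() < 0.8 else (0.001, "g")
                    if rng.random() < 0.15:
                        value *= 3
                    drugs.append((pid, drug.system, drug.code, value, unit, _ts(day_index, 9 + j)))
        for _ in range(int(rng.integers(0, 4))):
            o = OBSERVATIONS[0]
            if rng.random() < 0.15:
                observations.append(
                    (pid, o.system, o.code, None, None, "ABNORMAL", _ts(int(rng.integers(0, n_days)), 11))
                )
            else:
                observations.append(
                    (
                        pid,
                        o.system,
                        o.code,
                        float(rng.integers(80, 101)),
                        "%",
                        None,
                        _ts(int(rng.integers(0, n_days)), 11),
                    )
                )
    cohort = make_cohort(
        persons=persons,
        encounters=encounters,
        conditions=conditions,
        drugs=drugs,
        observations=observations,
        procedures=procedures,
    )
    window = EvaluationWindow(BASE, BASE + dt.timedelta(days=n_days - 1))
    return cohort, window
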