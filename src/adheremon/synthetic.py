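"""Seeded synthetic ICU cohort generator with known ground truth.

Emulates the setting in which an adherence monitor is typically exercised: a
COVID-19 ICU population over a pandemic period, where critically ill
patients requiring oxygen supply should receive a daily dexamethasone course,
and where the true adherence probability steps up at a configurable calendar
date (the moment the steroid evidence became public).  Admission dates are
drawn from a two-wave intensity (two Gaussian bumps) to mimic pandemic
waves; this shapes the time series but is irrelevant to correctness.

Each generated patient carries a ground-truth label (population member or
not; conformantly treated or not, and if not, the failure mode), which makes
the generator usable for parameter recovery: the evaluator, run blind on the
generated tables, should recover the configured adherence probabilities.

Non-conformant applicable patients are split round-robin into three failure
modes exercising the dosage semantics: no steroid at all, a wrong dose
(three times the recommended dose), and a gapped course (one day missing
mid-course).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical_data import CohortData, empty_table
from .evaluator import EvaluationWindow
from .model import (
    ConceptCode,
    Criterion,
    CriterionCombination,
    DosageSpec,
    Quantity,
    Recommendation,
)

#: Concepts used by the generated scenario.
COVID_CONDITION = ConceptCode(system="ICD10", code="U07.1", display="COVID-19")
OXYGEN_PROCEDURE = ConceptCode(system="SNOMED", code="57485005", display="Oxygen therapy")
DEXAMETHASONE = ConceptCode(system="ATC", code="H02AB02", display="Dexamethasone")
MILLIGRAM = ConceptCode(system="UCUM", code="mg")

#: Recommended course: one 1 mg dexamethasone administration per day, 10 days.
RECOMMENDED_DOSE_MG = 1.0
COURSE_DAYS = 10

#: Date of the first public announcement of the steroid trial result; default
#: step-change date of the two-wave scenario.
ANNOUNCEMENT_DATE = _dt.date(2020, 6, 16)

_DEFAULT_WINDOW = EvaluationWindow(_dt.date(2020, 3, 1), _dt.date(2021, 5, 31))


def dexamethasone_recommendation(
    dose_mg: float = RECOMMENDED_DOSE_MG,
    valid_from: _dt.date = ANNOUNCEMENT_DATE,
    version: str = "1.0",
) -> Recommendation:
    """The scenario's recommendation: critically ill COVID-19 patients
    requiring oxygen supply should receive daily dexamethasone for 10 days."""
    return Recommendation(
        id="covid19-dexamethasone",
        title="Dexamethasone for critically ill COVID-19 patients requiring oxygen supply",
        version=version,
        valid_from=valid_from,
        population=CriterionCombination(
            operator="ALL_OF",
            members=(
                Criterion(kind="condition", concept=COVID_CONDITION),
                Criterion(kind="procedure_active", concept=OXYGEN_PROCEDURE),
            ),
        ),
        intervention=CriterionCombination(
            operator="ALL_OF",
            members=(
                Criterion(
                    kind="drug_administration",
                    concept=DEXAMETHASONE,
                    dosage=DosageSpec(
                        dose=Quantity(value=dose_mg, unit=MILLIGRAM),
                        frequency_per_day=1,
                        duration_days=COURSE_DAYS,
                    ),
                ),
            ),
        ),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the two-wave adherence scenario.

    ``adherence_before``/``adherence_after`` are the probabilities that an
    applicable patient admitted before/after ``switch_date`` receives a
    guideline-conformant course; ``p_population`` is the probability that a
    patient meets the population criteria at all.
    """

    n_patients: int = 400
    window: EvaluationWindow = _DEFAULT_WINDOW
    p_population: float = 0.5
    adherence_before: float = 0.1
    adherence_after: float = 0.75
    switch_date: _dt.date = ANNOUNCEMENT_DATE
    mean_stay_days: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_population", "adherence_before", "adherence_after"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.mean_stay_days < 1:
            raise ValueError("mean_stay_days must be >= 1")
        lo = self.window.start_date - _dt.timedelta(days=1)
        hi = self.window.end_date + _dt.timedelta(days=1)
        if not lo <= self.switch_date <= hi:
            raise ValueError("switch_date must lie within or adjacent to the window")


@dataclass
class GroundTruth:
    """Per-patient generator labels for parameter recovery."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "person_id",
                "episode_start",
                "episode_days",
                "population_member",
                "conformant",
                "failure_mode",
                "course_start",
                "regime",
            ]
        )
    )


def _draw_admission(rng: np.random.Generator, window: EvaluationWindow) -> _dt.date:
    """Admission date from a two-Gaussian-bump intensity over the window."""
    span = window.n_days
    centers = (0.12 * span, 0.72 * span)  # early first wave, winter second wave
    center = centers[0] if rng.random() < 0.45 else centers[1]
    offset = int(round(rng.normal(center, 30.0)))
    offset = int(np.clip(offset, 0, span - 1))
    return window.start_date + _dt.timedelta(days=offset)


def generate(config: ScenarioConfig) -> tuple[CohortData, GroundTruth]:
    """Generate a synthetic cohort plus ground-truth labels, deterministically
    for a given seed.

    Episodes are ICU encounters with geometric stay lengths around
    ``mean_stay_days`` (clipped so each episode lies inside the window).
    Population members carry a COVID-19 condition and an oxygen-therapy
    procedure covering the whole episode; half of the non-members carry the
    condition without the oxygen requirement.  Conformant patients receive a
    once-daily 1 mg dexamethasone course from admission for
    ``min(10, stay)`` days.
    """
    rng = np.random.default_rng(config.seed)
    persons, encounters, conditions, procedures, drugs = [], [], [], [], []
    truth_rows = []
    n_nonconformant = 0  # round-robin counter over failure modes

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        admission = _draw_admission(rng, config.window)
        stay = int(rng.geometric(1.0 / config.mean_stay_days))
        max_stay = (config.window.end_date - admission).days + 1
        stay = max(1, min(stay, max_stay))
        start = _dt.datetime.combine(admission, _dt.time(0))
        end = start + _dt.timedelta(days=stay)

        persons.append((pid, int(rng.integers(1935, 1996)), "F" if rng.random() < 0.5 else "M"))
        encounters.append((pid, "ICU", start, end))

        is_member = bool(rng.random() < config.p_population)
        if is_member:
            conditions.append((pid, COVID_CONDITION.system, COVID_CONDITION.code, start, end))
            procedures.append((pid, OXYGEN_PROCEDURE.system, OXYGEN_PROCEDURE.code, start, end))
        elif rng.random() < 0.5:
            # COVID-19 without oxygen requirement: condition leaf true,
            # population ALL_OF still false
            conditions.append((pid, COVID_CONDITION.system, COVID_CONDITION.code, start, end))

        conformant = False
        failure_mode = ""
        course_start: _dt.date | None = None
        if is_member:
            p = (
                config.adherence_before
                if admission < config.switch_date
                else config.adherence_after
            )
            conformant = bool(rng.random() < p)
            course_len = min(COURSE_DAYS, stay)
            course_days = [admission + _dt.timedelta(days=k) for k in range(course_len)]
            if conformant:
                course_start = admission
                dose_days, dose = course_days, RECOMMENDED_DOSE_MG
            else:
                mode = ("absent", "wrong_dose", "gapped")[n_nonconformant % 3]
                n_nonconformant += 1
                failure_mode = mode
                if mode == "absent":
                    dose_days, dose = [], RECOMMENDED_DOSE_MG
                elif mode == "wrong_dose":
                    course_start = admission
                    dose_days, dose = course_days, RECOMMENDED_DOSE_MG * 3.0
                else:  # gapped: drop one day mid-course
                    course_start = admission
                    drop = len(course_days) // 2 if len(course_days) >= 3 else len(course_days) - 1
                    dose_days = [d for k, d in enumerate(course_days) if k != drop]
                    dose = RECOMMENDED_DOSE_MG
            for day in dose_days:
                at = _dt.datetime.combine(day, _dt.time(10))
                drugs.append((pid, DEXAMETHASONE.system, DEXAMETHASONE.code, dose, "mg", at))

        regime = "before" if admission < config.switch_date else "after"
        truth_rows.append(
            (pid, admission, stay, is_member, conformant, failure_mode, course_start, regime)
        )

    cohort = CohortData(
        persons=_frame("persons", persons, ["person_id", "birth_year", "sex"]),
        encounters=_frame("encounters", encounters, ["person_id", "ward_type", "start", "end"]),
        conditions=_frame(
            "conditions", conditions, ["person_id", "system", "code", "onset", "abatement"]
        ),
        procedures=_frame("procedures", procedures, ["person_id", "system", "code", "start", "end"]),
        drug_administrations=_frame(
            "drug_administrations",
            drugs,
            ["person_id", "system", "code", "dose_value", "dose_unit", "administered_at"],
        ),
    )
    truth = GroundTruth(
        table=pd.DataFrame(
            truth_rows,
            columns=[
                "person_id",
                "episode_start",
                "episode_days",
                "population_member",
                "conformant",
                "failure_mode",
                "course_start",
                "regime",
            ],
        )
    )
    return cohort, truth


def _frame(name: str, rows: list[tuple], columns: list[str]) -> pd.DataFrame:
    if not rows:
        return empty_table(name)
    frame = pd.DataFrame(rows, columns=columns)
    # match load_cohort dtypes so write/load round-trips to equality
    for col in columns:
        if col in ("start", "end", "onset", "abatement", "administered_at", "observed_at"):
            frame[col] = pd.to_datetime(frame[col])
        elif col == "dose_value":
            frame[col] = frame[col].astype("float64")
        elif col == "birth_year":
            frame[col] = frame[col].astype("int64")
    return frame
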