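"""Single-criterion evaluation semantics: intervals, closed world, negation,
observation comparators, unit handling."""

import datetime as dt

import pytest

from adheremon import (
    ConceptCode,
    Criterion,
    Quantity,
    UnitError,
    evaluate_criterion,
)
from adheremon.units import convert
from helpers import d, day, make_cohort

COVID = Criterion(kind="condition", concept=ConceptCode(system="ICD10", code="U07.1"))
OXY = Criterion(kind="procedure_active", concept=ConceptCode(system="SNOMED", code="57485005"))
DEXA = Criterion(kind="drug_administration", concept=ConceptCode(system="ATC", code="H02AB02"))
ICU = Criterion(kind="episode_attribute", concept=ConceptCode(system="SNOMED", code="ICU"))


def spo2_criterion(comparator, threshold):
    return Criterion(
        kind="observation",
        concept=ConceptCode(system="LOINC", code="59408-5"),
        comparator=comparator,
        threshold=Quantity(value=threshold, unit=ConceptCode(system="UCUM", code="%")),
    )


class TestConditionIntervals:
    def test_open_interval_covers_later_day(self):
        cohort = make_cohort(persons=["P1"], conditions=[("P1", "ICD10", "U07.1", d(3), None)])
        assert evaluate_criterion(COVID, cohort, "P1", day(5))

    def test_day_before_onset_not_covered(self):
        cohort = make_cohort(persons=["P1"], conditions=[("P1", "ICD10", "U07.1", d(3), None)])
        assert not evaluate_criterion(COVID, cohort, "P1", day(2))

    def test_half_open_end_at_midnight_excludes_that_day(self):
        cohort = make_cohort(persons=["P1"], conditions=[("P1", "ICD10", "U07.1", d(3), d(6))])
        assert evaluate_criterion(COVID, cohort, "P1", day(5))
        assert not evaluate_criterion(COVID, cohort, "P1", day(6))

    def test_end_within_day_still_covers_that_day(self):
        cohort = make_cohort(persons=["P1"], conditions=[("P1", "ICD10", "U07.1", d(3), d(6, 14))])
        assert evaluate_criterion(COVID, cohort, "P1", day(6))

    def test_onset_late_in_day_covers_that_day(self):
        cohort = make_cohort(persons=["P1"], conditions=[("P1", "ICD10", "U07.1", d(3, 23), None)])
        assert evaluate_criterion(COVID, cohort, "P1", day(3))


class TestClosedWorldAndNegation:
    def test_no_administration_is_false(self):
        cohort = make_cohort(persons=["P1"])
        assert not evaluate_criterion(DEXA, cohort, "P1", day(4))

    def test_negated_absence_is_true(self):
        cohort = make_cohort(persons=["P1"])
        negated = DEXA.model_copy(update={"negated": True})
        assert evaluate_criterion(negated, cohort, "P1", day(4))

    def test_administration_that_day_is_true(self):
        cohort = make_cohort(
            persons=["P1"], drugs=[("P1", "ATC", "H02AB02", 1.0, "mg", d(4, 10))]
        )
        assert evaluate_criterion(DEXA, cohort, "P1", day(4))
        assert not evaluate_criterion(DEXA, cohort, "P1", day(5))

    def test_unknown_person_errors(self):
        from adheremon import EvaluationError

        cohort = make_cohort(persons=["P1"])
        with pytest.raises(EvaluationError):
            evaluate_criterion(DEXA, cohort, "P9", day(4))


class TestProcedureAndEpisode:
    def test_procedure_active_interval(self):
        cohort = make_cohort(persons=["P1"], procedures=[("P1", "SNOMED", "57485005", d(2), d(8))])
        assert evaluate_criterion(OXY, cohort, "P1", day(7))
        assert not evaluate_criterion(OXY, cohort, "P1", day(8))

    def test_episode_attribute_matches_ward_type(self):
        cohort = make_cohort(persons=["P1"], encounters=[("P1", "ICU", d(1), d(4))])
        assert evaluate_criterion(ICU, cohort, "P1", day(3))
        assert not evaluate_criterion(ICU, cohort, "P1", day(4))
        normal = ICU.model_copy(
            update={"concept": ConceptCode(system="SNOMED", code="NORMAL")}
        )
        assert not evaluate_criterion(normal, cohort, "P1", day(3))


class TestObservation:
    @pytest.mark.parametrize(
        "comparator,threshold,value,expected",
        [
            ("<", 94.0, 92.0, True),
            ("<", 94.0, 94.0, False),
            ("<=", 94.0, 94.0, True),
            ("=", 94.0, 94.0, True),
            ("=", 94.0, 93.9, False),
            (">=", 94.0, 94.0, True),
            (">", 94.0, 94.0, False),
            (">", 94.0, 97.0, True),
        ],
    )
    def test_comparator_on_most_recent_value(self, comparator, threshold, value, expected):
        cohort = make_cohort(
            persons=["P1"],
            observations=[
                ("P1", "LOINC", "59408-5", 99.0, "%", None, d(1, 8)),
                ("P1", "LOINC", "59408-5", value, "%", None, d(2, 8)),
            ],
        )
        crit = spo2_criterion(comparator, threshold)
        assert evaluate_criterion(crit, cohort, "P1", day(3)) is expected

    def test_most_recent_wins_not_any(self):
        cohort = make_cohort(
            persons=["P1"],
            observations=[
                ("P1", "LOINC", "59408-5", 90.0, "%", None, d(1, 8)),
                ("P1", "LOINC", "59408-5", 97.0, "%", None, d(2, 8)),
            ],
        )
        assert not evaluate_criterion(spo2_criterion("<", 94.0), cohort, "P1", day(2))
        assert evaluate_criterion(spo2_criterion("<", 94.0), cohort, "P1", day(1))

    def test_no_observation_is_false(self):
        cohort = make_cohort(persons=["P1"])
        assert not evaluate_criterion(spo2_criterion("<", 94.0), cohort, "P1", day(3))

    def test_code_valued_result_is_false_for_numeric_comparator(self):
        cohort = make_cohort(
            persons=["P1"],
            observations=[("P1", "LOINC", "59408-5", None, None, "LOW", d(1, 8))],
        )
        assert not evaluate_criterion(spo2_criterion("<", 94.0), cohort, "P1", day(2))

    def test_incomparable_units_error_names_both(self):
        cohort = make_cohort(
            persons=["P1"],
            observations=[("P1", "LOINC", "59408-5", 92.0, "mg", None, d(1, 8))],
        )
        with pytest.raises(UnitError, match="mg"):
            evaluate_criterion(spo2_criterion("<", 94.0), cohort, "P1", day(2))


class TestUnits:
    @pytest.mark.parametrize(
        "value,from_u,to_u,expected",
        [(1.0, "g", "mg", 1000.0), (500.0, "ug", "mg", 0.5), (2.0, "d", "h", 48.0), (5.0, "%", "%", 5.0)],
    )
    def test_conversion_table(self, value, from_u, to_u, expected):
        assert convert(value, from_u, to_u) == pytest.approx(expected)

    def test_cross_group_errors(self):
        with pytest.raises(UnitError):
            convert(1.0, "mg", "%")

    def test_unknown_unit_errors(self):
        with pytest.raises(UnitError):
            convert(1.0, "mL", "mg")

    def test_dose_in_grams_matches_mg_criterion(self):
        cohort = make_cohort(
            persons=["P1"], drugs=[("P1", "ATC", "H02AB02", 0.001, "g", d(4, 10))]
        )
        from adheremon import DosageSpec

        crit = DEXA.model_copy(
            update={
                "dosage": DosageSpec(
                    dose=Quantity(value=1.0, unit=ConceptCode(system="UCUM", code="mg")),
                    frequency_per_day=1,
                    duration_days=10,
                )
            }
        )
        assert evaluate_criterion(crit, cohort, "P1", day(4))
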