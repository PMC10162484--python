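"""Patient- and cohort-level evaluation: encounter gating, aggregation,
invariants, and content-only recommendation updates."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from adheremon import (
    CriterionCombination,
    EvaluationWindow,
    compile,
    evaluate_cohort,
    evaluate_patient,
    select_version,
)
from adheremon.synthetic import dexamethasone_recommendation
from helpers import d, day, make_cohort
from instgen import random_cohort, random_criterion


@pytest.fixture
def plan(dexa_rec):
    return compile(dexa_rec)


class TestEvaluatePatient:
    def test_saturated_patient_adherent_all_days(self, plan):
        window = EvaluationWindow(day(1), day(10))
        cohort = make_cohort(
            persons=["P1"],
            encounters=[("P1", "ICU", d(1), None)],
            conditions=[("P1", "ICD10", "U07.1", d(1), None)],
            procedures=[("P1", "SNOMED", "57485005", d(1), None)],
            drugs=[("P1", "ATC", "H02AB02", 1.0, "mg", d(k, 10)) for k in range(1, 11)],
        )
        results = evaluate_patient(plan, cohort, "P1", window)
        assert len(results) == 10
        assert all(r.adherent for r in results)

    def test_never_admitted_never_applicable(self, plan):
        window = EvaluationWindow(day(1), day(10))
        cohort = make_cohort(
            persons=["P1"],
            conditions=[("P1", "ICD10", "U07.1", d(1), None)],
            procedures=[("P1", "SNOMED", "57485005", d(1), None)],
        )
        results = evaluate_patient(plan, cohort, "P1", window)
        assert not any(r.population_applicable for r in results)

    def test_course_from_day_5_adherent_days_5_to_14(self, plan, simple_cohort):
        """20-day applicable window, 10-day course from day 5: adherent on
        exactly days 5-14."""
        window = EvaluationWindow(day(1), day(20))
        results = evaluate_patient(plan, simple_cohort, "P1", window)
        adherent_days = {r.date for r in results if r.adherent}
        assert adherent_days == {day(n) for n in range(5, 15)}
        applicable_days = {r.date for r in results if r.population_applicable}
        assert applicable_days == {day(n) for n in range(1, 21)}

    def test_adherent_implies_applicable_by_construction(self, plan, simple_cohort):
        window = EvaluationWindow(day(1), day(25))
        for r in evaluate_patient(plan, simple_cohort, "P1", window):
            assert r.adherent == (r.population_applicable and r.intervention_fulfilled)

    def test_unknown_person_errors(self, plan, simple_cohort):
        from adheremon import EvaluationError

        with pytest.raises(EvaluationError):
            evaluate_patient(plan, simple_cohort, "P9", EvaluationWindow(day(1), day(2)))


class TestEvaluateCohort:
    def test_counting(self, plan):
        """3 applicable patients, 2 adherent on the queried day."""
        window = EvaluationWindow(day(5), day(5))

        def patient(pid, treated):
            return dict(
                persons=[pid],
                encounters=[(pid, "ICU", d(1), None)],
                conditions=[(pid, "ICD10", "U07.1", d(1), None)],
                procedures=[(pid, "SNOMED", "57485005", d(1), None)],
                drugs=[(pid, "ATC", "H02AB02", 1.0, "mg", d(k, 10)) for k in range(1, 11)]
                if treated
                else [],
            )

        parts = [patient("P1", True), patient("P2", True), patient("P3", False)]
        cohort = make_cohort(
            persons=[p for part in parts for p in part["persons"]],
            encounters=[e for part in parts for e in part["encounters"]],
            conditions=[c for part in parts for c in part["conditions"]],
            procedures=[c for part in parts for c in part["procedures"]],
            drugs=[c for part in parts for c in part["drugs"]],
        )
        res = evaluate_cohort(plan, cohort, window)
        row = res.series.iloc[0]
        assert row.n_applicable == 3
        assert row.n_adherent == 2
        assert row.fraction == pytest.approx(2 / 3)

    def test_empty_cohort_all_zero_null_fractions(self, plan):
        res = evaluate_cohort(plan, make_cohort(), EvaluationWindow(day(1), day(5)))
        assert (res.series["n_applicable"] == 0).all()
        assert res.series["fraction"].isna().all()

    def test_deterministic(self, plan, simple_cohort, march_window):
        a = evaluate_cohort(plan, simple_cohort, march_window)
        b = evaluate_cohort(plan, simple_cohort, march_window)
        assert a.series.equals(b.series)
        assert a.day_results.equals(b.day_results)

    def test_subset_law_on_random_instances(self, plan):
        """n_adherent <= n_applicable on every day of random cohorts."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cohort, window = random_cohort(rng, max_patients=10, n_days=15)
            res = evaluate_cohort(plan, cohort, window)
            assert (res.series["n_adherent"] <= res.series["n_applicable"]).all()

    def test_monotonicity_all_of_never_gains_applicable(self, dexa_rec):
        """Appending a criterion under the ALL_OF population never increases
        any day's applicable count; under ANY_OF it never decreases it."""
        rng = np.random.default_rng(3)
        for seed in range(8):
            cohort, window = random_cohort(np.random.default_rng(seed), max_patients=10, n_days=15)
            extra = random_criterion(rng)
            base = evaluate_cohort(compile(dexa_rec), cohort, window).series
            all_of = dexa_rec.model_copy(
                update={
                    "population": CriterionCombination(
                        operator="ALL_OF", members=tuple(dexa_rec.population.members) + (extra,)
                    )
                }
            )
            tightened = evaluate_cohort(compile(all_of), cohort, window).series
            assert (tightened["n_applicable"] <= base["n_applicable"]).all()
            any_of = dexa_rec.model_copy(
                update={
                    "population": CriterionCombination(
                        operator="ANY_OF", members=(dexa_rec.population, extra)
                    )
                }
            )
            widened = evaluate_cohort(compile(any_of), cohort, window).series
            assert (widened["n_applicable"] >= base["n_applicable"]).all()


class TestGuidelineUpdate:
    """Content-only updates: new recommendation JSON, zero engine changes."""

    def _two_dose_cohort(self):
        # P-lo receives 1 mg daily, P-hi receives 2 mg daily; both applicable
        def rows(pid, dose):
            return dict(
                persons=[pid],
                encounters=[(pid, "ICU", d(1), None)],
                conditions=[(pid, "ICD10", "U07.1", d(1), None)],
                procedures=[(pid, "SNOMED", "57485005", d(1), None)],
                drugs=[(pid, "ATC", "H02AB02", dose, "mg", d(k, 10)) for k in range(1, 11)],
            )

        lo, hi = rows("P-lo", 1.0), rows("P-hi", 2.0)
        return make_cohort(
            persons=lo["persons"] + hi["persons"],
            encounters=lo["encounters"] + hi["encounters"],
            conditions=lo["conditions"] + hi["conditions"],
            procedures=lo["procedures"] + hi["procedures"],
            drugs=lo["drugs"] + hi["drugs"],
        )

    def test_version_swap_flips_exactly_dose_mismatched_patients(self):
        cohort = self._two_dose_cohort()
        window = EvaluationWindow(day(1), day(10))
        v1 = dexamethasone_recommendation(dose_mg=1.0, version="1.0")
        v2 = dexamethasone_recommendation(dose_mg=2.0, version="2.0")
        res1 = evaluate_cohort(compile(v1), cohort, window).day_results
        res2 = evaluate_cohort(compile(v2), cohort, window).day_results

        def adherent_set(res):
            return set(res[res["adherent"]]["person_id"])

        assert adherent_set(res1) == {"P-lo"}
        assert adherent_set(res2) == {"P-hi"}
        # applicability is untouched by the intervention change
        assert res1["population_applicable"].equals(res2["population_applicable"])

    def test_select_version_per_day_reproduces_step_at_boundary(self):
        cohort = self._two_dose_cohort()
        boundary = day(6)
        v1 = dexamethasone_recommendation(dose_mg=1.0, valid_from=day(1), version="1.0")
        v2 = dexamethasone_recommendation(dose_mg=2.0, valid_from=boundary, version="2.0")
        versions = [v1, v2]
        plans = {r.version: compile(r) for r in versions}
        adherent_by_day = {}
        for n in range(1, 11):
            rec = select_version(versions, day(n))
            res = evaluate_cohort(plans[rec.version], cohort, EvaluationWindow(day(n), day(n)))
            adherent_by_day[day(n)] = set(
                res.day_results[res.day_results["adherent"]]["person_id"]
            )
        for n in range(1, 11):
            expected = {"P-lo"} if day(n) < boundary else {"P-hi"}
            assert adherent_by_day[day(n)] == expected, n
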