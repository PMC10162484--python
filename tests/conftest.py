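import datetime as dt
import json

import pytest

from adheremon import (
    EvaluationWindow,
    dexamethasone_recommendation,
    serialize_recommendation,
    write_cohort,
)
from helpers import d, make_cohort


@pytest.fixture
def dexa_rec():
    """The worked recommendation: COVID-19 + oxygen supply -> daily 1 mg
    dexamethasone for 10 days."""
    return dexamethasone_recommendation()


@pytest.fixture
def dexa_json(dexa_rec):
    return serialize_recommendation(dexa_rec)


@pytest.fixture
def dexa_doc(dexa_json):
    return json.loads(dexa_json)


@pytest.fixture
def march_window():
    return EvaluationWindow(dt.date(2020, 3, 1), dt.date(2020, 3, 30))


@pytest.fixture
def simple_cohort():
    """One ICU patient, COVID + oxygen days 1-20, 10-day 1 mg course from day 5."""
    return make_cohort(
        persons=["P1"],
        encounters=[("P1", "ICU", d(1), d(21))],
        conditions=[("P1", "ICD10", "U07.1", d(1), d(21))],
        procedures=[("P1", "SNOMED", "57485005", d(1), d(21))],
        drugs=[
            ("P1", "ATC", "H02AB02", 1.0, "mg", d(5 + k, 10)) for k in range(10)
        ],
    )


@pytest.fixture
def cohort_dir(tmp_path, simple_cohort):
    path = tmp_path / "cohort"
    write_cohort(simple_cohort, path)
    return path
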