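# adheremon

Automated monitoring of adherence to evidence-based clinical guideline
recommendations against electronic health record data.

Hospitals — intensive care units in particular — face many simultaneously
applicable guideline recommendations that change quickly as evidence
accrues.  `adheremon` is a rule engine for clinicians, quality managers and
health-data engineers that answers, for every patient and every calendar
day: *does this recommendation apply to this patient today, and is it being
followed?*

## The model

A recommendation is written declaratively following the PICO decomposition
of clinical questions.  The engine uses the **P** (population) and **I**
(intervention) parts, each a boolean tree (`ALL_OF` / `ANY_OF`, optionally
negated) of terminology-coded criteria (ICD-10, SNOMED CT, ATC, LOINC,
UCUM):

- *population applicable* on day *t*:  patient admitted on *t* ∧ P(patient, *t*)
- *intervention fulfilled* on day *t*:  I(patient, *t*)
- *adherent* on day *t*:  applicable ∧ fulfilled

Criteria test conditions and procedure/therapy episodes (half-open
`[start, end)` intervals), drug administrations (optionally against a
dosing schedule: dose × frequency per day × course duration, with a
relative dose tolerance, default 10%), and observations (comparator
against the most recent value, after UCUM unit normalization).  Evaluation
is closed-world — absence of a record makes a criterion false — and fully
deterministic.

Because the recommendation is data, updating a guideline means swapping a
JSON document: the engine code never changes (`select_version` picks the
version in force on each day).  Clinical data enter through a common
tabular data model (six CSV tables: persons, encounters, conditions, drug
administrations, observations, procedures); a concept map translates
guideline codes to the codes used in the local data.

The package also ships a seeded synthetic-cohort generator that emulates an
ICU COVID-19 cohort with oxygen-requirement episodes, daily dexamethasone
courses and a configurable true adherence probability that steps up at a
configurable date (the two-wave pandemic scenario), with per-patient ground
truth for parameter-recovery experiments.

## Worked example

The repository bundles a 5-patient example (`examples/`): the worked
recommendation — ICU patients with COVID-19 (ICD-10 U07.1) requiring oxygen
supply (SNOMED 57485005) should receive one 1 mg dexamethasone (ATC
H02AB02) administration daily for 10 days:

```sh
adheremon evaluate \
  --recommendation examples/recommendation.json \
  --cohort examples/cohort \
  --codemap examples/codemap.csv \
  --start 2020-03-01 --end 2020-03-10 \
  --out out/
head -6 out/series.csv
```

```
date,n_applicable,n_adherent,fraction
2020-03-01,2,1,0.500000
2020-03-02,2,1,0.500000
2020-03-03,3,2,0.666667
2020-03-04,3,2,0.666667
2020-03-05,3,1,0.333333
```

Reading the fixture: P1 is admitted with COVID-19 on oxygen and treated
correctly all 10 days (always adherent); P2 is applicable but untreated; P3
has COVID-19 but no oxygen requirement (never applicable); P4 is admitted
days 3–8 and treated except for a gap on day 5 — on that day no conformant
course covers them, so `n_adherent` drops from 2 to 1; P5 is never
admitted, so the recommendation does not apply.  `day_results.csv` holds
the per-patient verdicts, and `leaf_results.csv` the per-criterion audit
trail from which every verdict can be re-derived.

A synthetic two-wave scenario runs with:

```sh
adheremon synthesize --config examples/scenario.yaml --out synth/ --evaluate
```

which writes the generated cohort, its ground-truth labels, the evaluation
outputs and `synth/evaluation/regime_summary.json` with the patient-level
adherence fraction before and after the step date.

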