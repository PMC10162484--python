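# Methods

## Problem and model

`adheremon` evaluates, at calendar-day granularity, whether a guideline
recommendation (a) applies to a patient and (b) is being followed.  A
recommendation is a pure data object: metadata (`id`, `title`, `version`,
`valid_from`) plus two criterion trees following the PICO decomposition —
the population (P) and the intervention (I).  Comparison and outcome
elements may appear in a document but are ignored by the engine; adherence
is defined on P and I alone.  Each criterion carries a standard terminology
code, which is what makes the engine content-agnostic: compiling a
recommendation binds each leaf to local data codes through a concept map
and produces an executable rule tree; no recommendation-specific code
exists anywhere.

Day-level verdicts are:

- `population_applicable(t)` = admitted(t) ∧ P(t).  The admission gate is
  deliberate: a recommendation is only actionable for patients currently in
  care, and ward-level monitoring is organized around admitted patients.
- `intervention_fulfilled(t)` = I(t), evaluated regardless of admission so
  the two outputs stay independently interpretable.
- `adherent(t)` = both.

Day granularity matches both how dosing recommendations are phrased
("daily administration …") and how cohort adherence time series are read;
sub-day timing of events only matters through the half-open interval
convention below.

## Evaluation semantics

**Closed world.**  A criterion with no matching record is false (before
negation).  Three-valued logic was considered and rejected: without a
notion of "data expected but missing", unknowns collapse into false anyway,
and a conservative false keeps the adherent count an underestimate rather
than an overestimate.  The per-criterion audit trail (`leaf_results.csv`)
is the mitigation: every verdict can be traced to the presence or absence
of specific records.

**Intervals.**  All episodes (conditions, procedures, encounters) are
half-open `[start, end)`; an episode ending at 00:00 of day *d* does not
cover *d*.  Date-only timestamps mean 00:00.  An absent end means the
episode is still open and extends to the end of the evaluation window.

**Observations.**  The most recent matching observation at or before the
end of the query day is compared against the threshold after unit
conversion.  A code-valued result cannot satisfy a numeric comparator and
yields false; units from different dimension groups raise an error naming
both units (silently treating 92 mg as 92 % would be worse than failing).

**Units.**  A fixed UCUM subset is supported: µg/mg/g (mass), % and h/d.
This covers dose checking and common vital-sign thresholds; a full UCUM
grammar is out of scope and would add no tested behaviour.

**Dosing courses.**  A drug criterion with a schedule (dose *per
administration*, `frequency_per_day`, `duration_days`) is fulfilled on day
*t* iff a conformant course covers *t*:

- A *course start* is an administration day with no matching administration
  the day before — the first day of an administration run.  A new course
  may therefore begin after an interruption; a gap day itself is never
  covered, and no course "spans" a gap.
- A course starting on *s* covers *t* iff `s ≤ t < s + duration_days` and
  every day in `[s, t]` has exactly `frequency_per_day` administrations
  whose total dose lies within a relative tolerance (default 0.10,
  configurable) of the recommended daily total.  Exact float equality would
  be wrong under clinical rounding; 10% separates rounding from clinically
  distinct dosing.
- Days are judged without lookahead ("ongoing-adherent"): mid-course days
  count as fulfilled even if the course later fails or is abandoned.  The
  alternative — requiring the course to eventually complete — would make
  today's verdict depend on future data, which a monitoring system cannot
  have.  Days of a run beyond the recommended duration are not covered, so
  an over-long course is non-conformant on its tail; days after a completed
  course are likewise not fulfilled.

**Versioning.**  `select_version` returns the version with the latest
`valid_from` not after the query date (inclusive: a recommendation released
on a day applies on that day).  Applying it per evaluation day reproduces a
step change in verdicts at a version boundary with zero engine changes.

## Data model and terminology mapping

Clinical data enter as six CSV tables (persons, encounters, conditions,
drug administrations, observations, procedures) — a deliberately minimal
common data model; OMOP-, FHIR- or openEHR-based sources can feed it
through thin exporters.  Loading is strict: rows violating invariants
(orphan person ids, inverted intervals, non-positive doses, both-or-neither
observation values) are rejected with located errors rather than silently
coerced, and `validate_cohort` returns the same checks as machine-readable
findings without raising.

The concept map is strict by default: an unmapped guideline code is a
compile-time error naming the criterion path, because a silently unmatched
code would produce plausible-looking false "not applicable" verdicts.
One-to-many mappings are disjunctive (any local code satisfies the
concept); mappings are flat code lists — hierarchy/subsumption expansion
belongs to a terminology server, not this engine.

## Synthetic cohort generator

The generator emulates the setting the engine targets: an ICU COVID-19
cohort over March 2020 – May 2021 with a recommendation step date of
2020-06-16 (the public announcement of the steroid-trial result).  Defaults:
400 patients, population probability 0.5, adherence probability 0.10 before
and 0.75 after the step, mean stay 10 days.

Per patient: an admission date from a two-Gaussian-bump intensity (the two
pandemic waves; cosmetic for time-series plots, irrelevant to correctness),
a geometric stay length clipped so the episode lies inside the window, and
an ICU encounter.  Population members carry a COVID-19 condition and an
oxygen-therapy procedure covering the episode; half of the non-members
carry the condition without the oxygen requirement, so conjunctions are
genuinely exercised.  Applicable patients are conformant with the
regime-dependent probability; conformant patients receive one 1 mg
dexamethasone administration daily from admission for `min(10, stay)` days.
Non-conformant patients split round-robin into three failure modes chosen
to exercise each branch of the dosing semantics: no steroid, triple dose,
and a one-day gap mid-course.

What the generator does **not** emulate: transfer patients treated before
arrival (their pre-admission administrations are simply absent, as in real
single-site data), comorbidity structure, pharmacokinetics, dose titration,
and observation streams.  Passing tests therefore demonstrate the engine's
logical correctness and parameter recovery under clean data — not
robustness to real-world coding noise, which the strict loader surfaces
rather than repairs.

## Parameter recovery measurement

Cohort-level daily fractions (the time-series output) mix course-length
effects with adherence: a conformant patient with a 20-day stay is adherent
on only the 10 course days.  Recovery is therefore measured patient-level:
a patient with at least one applicable day counts as adherent iff their
number of adherent days reaches `min(duration_days, applicable days)` —
i.e. the course covered every day it should have, given the length of stay.
Under the generator this classification recovers the conformance label
exactly (a gapped course misses exactly its gap day and fails the bar), so
the per-regime adherent count is exactly binomial, and the acceptance check
compares it against the exact central 95% binomial interval of the
configured rate across 20 fixed seeds.  Regime assignment uses the first
applicable day relative to the step date.

## Numerical and degenerate-input choices

- No randomness anywhere in evaluation; all generator randomness flows from
  one `numpy` Generator seeded from the scenario seed.
- Daily-fraction `fraction` is null (empty CSV field / JSON null) on days
  with zero applicable patients, never 0/0.
- Equality comparator on observations uses a 1e-9 relative tolerance; dose
  tolerance is inclusive at the boundary.
- Empty cohorts, empty event tables and `n_patients = 0` are valid inputs
  producing empty-but-schema-correct outputs.
- Serialization is canonical: fixed key order, fixed float formatting, so
  equal objects produce byte-identical files.  The run report's timestamp
  is the single intentionally non-deterministic output field; all CSV
  outputs are byte-reproducible.

## Test design and problem sizes

The engine is checked against independent references rather than against
itself: a brute-force per-(patient, day, leaf) evaluator with its own unit
table and literal course-start enumeration (`tests/oracle.py`), exact
binomial envelopes from the generator's ground truth, and hand-computed
verdicts on the bundled 5-patient fixture.  Randomized checks use 200
instances of up to 20 patients × 30 days for engine-vs-oracle equivalence,
500+ instance-days for the subset/monotonicity laws, 20 seeds of the
400-patient scenario for recovery, and 100 objects per serialization
round-trip family — sizes at which the brute-force references remain exact
and the whole suite runs in a few minutes on one CPU.

## Known limitations

- Single-recommendation, single-step semantics: multi-step clinical
  pathways with decision points are not representable.
- No uncertainty or evidence-certainty handling; verdicts are binary.
- Flat terminology mapping (no subsumption); no terminology-server
  integration.
- The admission gate means pre-admission treatment (transfers) depresses
  measured adherence — a faithful property of single-site data, not a bug
  the engine corrects.
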