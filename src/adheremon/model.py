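"""Machine-readable guideline recommendation model.

A guideline recommendation is represented declaratively, following the PICO
decomposition of evidence-based recommendations: a *population* criterion
tree (the P — who the recommendation applies to) and an *intervention*
criterion tree (the I — what is recommended for those patients).  Every
clinical concept in a criterion is coded with a standard terminology
(ICD-10, SNOMED CT, ATC, LOINC, or UCUM), which is what lets a single
evaluation engine execute arbitrary recommendation content without code
changes: updating the recommendation means swapping the JSON document, not
the software.

The JSON dialect is a self-contained flat schema
``{id, title, version, valid_from, population, intervention}``; comparison
("C") and outcome ("O") elements may be present in a document but are
ignored by the engine, which evaluates applicability and adherence from P
and I alone.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .errors import SchemaError
from .units import SUPPORTED_UNITS

logger = logging.getLogger(__name__)

#: Closed set of supported terminology systems.
TerminologySystem = Literal["ICD10", "SNOMED", "ATC", "LOINC", "UCUM"]

Comparator = Literal["<", "<=", "=", ">=", ">"]

CriterionKind = Literal[
    "condition",
    "drug_administration",
    "observation",
    "procedure_active",
    "episode_attribute",
]


class ConceptCode(BaseModel):
    """A terminology-coded clinical concept, e.g. ``(ICD10, U07.1)``."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    system: TerminologySystem
    code: str = Field(min_length=1)
    display: Optional[str] = None

    def key(self) -> tuple[str, str]:
        """The (system, code) pair identifying this concept; display is a label only."""
        return (self.system, self.code)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.system}|{self.code}"


class Quantity(BaseModel):
    """A numeric value with a UCUM unit (drug dose, lab value, threshold)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    value: float
    unit: ConceptCode

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("quantity value must be finite")
        return v

    @field_validator("unit")
    @classmethod
    def _ucum(cls, u: ConceptCode) -> ConceptCode:
        if u.system != "UCUM":
            raise ValueError("quantity unit must use the UCUM system")
        if u.code not in SUPPORTED_UNITS:
            raise ValueError(
                f"unsupported UCUM unit {u.code!r}; supported: {sorted(SUPPORTED_UNITS)}"
            )
        return u


class DosageSpec(BaseModel):
    """A dosing schedule: dose per administration, administrations per day,
    and course duration in days (or ``"unbounded"`` for open-ended therapy)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    dose: Quantity
    frequency_per_day: int = Field(ge=1)
    duration_days: Union[int, Literal["unbounded"]] = "unbounded"

    @field_validator("duration_days")
    @classmethod
    def _positive(cls, v):
        if isinstance(v, int) and v < 1:
            raise ValueError("duration_days must be >= 1 when bounded")
        return v

    @property
    def bounded(self) -> bool:
        return self.duration_days != "unbounded"


class Criterion(BaseModel):
    """A single terminology-coded clinical test.

    ``kind`` selects the evaluation semantics:

    - ``condition``: a diagnosis interval covers the day;
    - ``drug_administration``: an administration occurred that day (or, with a
      :class:`DosageSpec`, a conformant course covers the day);
    - ``observation``: the most recent observation satisfies ``comparator``
      against ``threshold``;
    - ``procedure_active``: a procedure/therapy episode covers the day;
    - ``episode_attribute``: an encounter of the coded ward type covers the day.

    ``negated`` flips the result after closed-world evaluation.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: CriterionKind
    concept: ConceptCode
    dosage: Optional[DosageSpec] = None
    comparator: Optional[Comparator] = None
    threshold: Optional[Quantity] = None
    negated: bool = False

    @model_validator(mode="after")
    def _kind_consistency(self) -> "Criterion":
        if self.dosage is not None and self.kind != "drug_administration":
            raise ValueError("dosage is only allowed for drug_administration criteria")
        has_cmp = self.comparator is not None
        has_thr = self.threshold is not None
        if self.kind == "observation":
            if not (has_cmp and has_thr):
                raise ValueError("observation criteria require comparator and threshold")
        elif has_cmp or has_thr:
            raise ValueError("comparator/threshold are only allowed for observation criteria")
        return self


class CriterionCombination(BaseModel):
    """A boolean grouping of criteria: ``ALL_OF`` (conjunction) or
    ``ANY_OF`` (disjunction), optionally negated, with arbitrary nesting."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    operator: Literal["ALL_OF", "ANY_OF"]
    members: tuple[Union["Criterion", "CriterionCombination"], ...] = Field(min_length=1)
    negated: bool = False


CriterionNode = Union[Criterion, CriterionCombination]


class Recommendation(BaseModel):
    """A versioned guideline recommendation: metadata plus the population
    (P) and intervention (I) criterion trees."""

    # extra="ignore": documents may carry comparison/outcome elements or
    # other metadata; the engine evaluates P and I only.
    model_config = ConfigDict(extra="ignore", frozen=True)

    id: str = Field(min_length=1)
    title: str
    version: str
    valid_from: _dt.date
    population: CriterionCombination
    intervention: CriterionCombination


#: Field order used for deterministic serialization.
_TOP_LEVEL_FIELDS = ("id", "title", "version", "valid_from", "population", "intervention")


def _loc_to_path(loc: tuple) -> str:
    parts = []
    for item in loc:
        # pydantic tags union branches with the class name; drop those.
        if isinstance(item, str) and item in ("Criterion", "CriterionCombination"):
            continue
        parts.append(str(item))
    return "/" + "/".join(parts) if parts else "/"


def parse_recommendation(document: str) -> Recommendation:
    """Parse and validate a recommendation JSON document.

    Unknown top-level fields are ignored with a logged warning (this is how
    comparison/outcome elements and future metadata pass through).  Any
    structural problem raises :class:`~adheremon.errors.SchemaError` naming
    the JSON path of the first offending element.
    """
    try:
        raw = json.loads(document)
    except json.JSONDecodeError as exc:
        raise SchemaError("/", f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError("/", "recommendation document must be a JSON object")
    extras = set(raw) - set(_TOP_LEVEL_FIELDS)
    if extras:
        logger.warning("ignoring unknown top-level fields: %s", sorted(extras))
    try:
        return Recommendation.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        raise SchemaError(_loc_to_path(first["loc"]), first["msg"]) from exc


def serialize_recommendation(rec: Recommendation) -> str:
    """Serialize a recommendation to canonical JSON text.

    The output is deterministic (fixed key order, fixed formatting) and
    round-trips: ``parse_recommendation(serialize_recommendation(r)) == r``.
    """
    data = rec.model_dump(mode="json", exclude_none=True)
    ordered = {k: data[k] for k in _TOP_LEVEL_FIELDS}
    return json.dumps(ordered, indent=2, ensure_ascii=False) + "\n"


def select_version(
    versions: list[Recommendation], on_date: _dt.date
) -> Optional[Recommendation]:
    """Select the recommendation version in force on ``on_date``.

    Returns the version with the latest ``valid_from`` not after ``on_date``
    (the boundary is inclusive: a version is in force on its own
    ``valid_from`` day), or ``None`` if no version is yet valid.  All
    versions must share one recommendation id.
    """
    if not versions:
        return None
    ids = {v.id for v in versions}
    if len(ids) > 1:
        raise ValueError(f"select_version requires a single recommendation id, got {sorted(ids)}")
    valid = [v for v in versions if v.valid_from <= on_date]
    if not valid:
        return None
    return max(valid, key=lambda v: v.valid_from)


def recommendation_json_schema() -> dict:
    """The JSON Schema (draft 2020-12) of the recommendation document format."""
    return Recommendation.model_json_schema()
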