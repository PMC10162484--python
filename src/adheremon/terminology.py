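"""Concept mapping between guideline codes and local patient-data codes.

Guideline recommendations are coded with standard terminologies, but a
hospital's data may use different (local or more granular) codes for the
same concepts.  Before criterion evaluation, each guideline concept is
resolved to the list of local codes that realize it.  One-to-many mappings
are interpreted as OR: any local code matching satisfies the concept.

By default the map is *strict*: an unmapped guideline concept is an error
rather than a silent "never matches", because a silently unmatched code
would yield false "not applicable" verdicts that clinicians cannot detect.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DataFormatError, TerminologyError
from .model import ConceptCode

logger = logging.getLogger(__name__)


@dataclass
class CodeMap:
    """Mapping from guideline concepts to local data concepts."""

    entries: dict[tuple[str, str], list[ConceptCode]] = field(default_factory=dict)
    strict: bool = True

    def __post_init__(self) -> None:
        for key, codes in self.entries.items():
            if not codes:
                raise ValueError(f"code map entry {key} maps to an empty list")


def load_codemap(csv_path: str | Path, strict: bool = True) -> CodeMap:
    """Load a concept map from CSV.

    Expected header: ``guideline_system,guideline_code,local_system,local_code``.
    Multiple rows with the same guideline code aggregate into one entry with
    several local codes; exact duplicate rows are dropped with a warning.
    """
    path = Path(csv_path)
    if not path.is_file():
        raise DataFormatError(f"code map file not found: {path}")
    expected = ["guideline_system", "guideline_code", "local_system", "local_code"]
    entries: dict[tuple[str, str], list[ConceptCode]] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise DataFormatError(f"{path.name}: empty file (expected header)") from None
        if header != expected:
            raise DataFormatError(
                f"{path.name}: header must be {','.join(expected)}, got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 4 or any(not cell.strip() for cell in row):
                raise DataFormatError(f"{path.name} line {lineno}: malformed row {row!r}")
            g_sys, g_code, l_sys, l_code = (cell.strip() for cell in row)
            try:
                local = ConceptCode(system=l_sys, code=l_code)
                ConceptCode(system=g_sys, code=g_code)
            except Exception as exc:
                raise DataFormatError(f"{path.name} line {lineno}: {exc}") from exc
            key = (g_sys, g_code)
            bucket = entries.setdefault(key, [])
            if local in bucket:
                logger.warning("%s line %d: duplicate mapping row ignored", path.name, lineno)
                continue
            bucket.append(local)
    return CodeMap(entries=entries, strict=strict)


def resolve(codemap: CodeMap, concept: ConceptCode) -> list[ConceptCode]:
    """Resolve a guideline concept to its local data codes.

    With no entry present: strict maps raise
    :class:`~adheremon.errors.TerminologyError`; lenient maps fall back to
    the identity mapping (the concept itself) with a logged warning, so the
    result is never empty in non-strict mode.
    """
    entry = codemap.entries.get(concept.key())
    if entry is not None:
        return list(entry)
    if codemap.strict:
        raise TerminologyError(
            f"no mapping for guideline concept {concept.system}|{concept.code} (strict mode)"
        )
    logger.warning(
        "no mapping for %s|%s; falling back to identity", concept.system, concept.code
    )
    return [concept]


def identity_codemap(strict: bool = False) -> CodeMap:
    """A lenient empty map: every concept resolves to itself."""
    return CodeMap(entries={}, strict=strict)
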