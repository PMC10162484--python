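"""Exception hierarchy for adheremon.

All errors raised by the library derive from :class:`AdheremonError` so that
callers (and the CLI) can catch everything the engine may raise with one
``except`` clause while still distinguishing the failure class.
"""

from __future__ import annotations


class AdheremonError(Exception):
    """Base class for all adheremon errors."""


class SchemaError(AdheremonError):
    """A recommendation document violates the schema.

    Parameters
    ----------
    path:
        JSON-pointer-style path to the offending element, e.g.
        ``"/intervention/members/0/dosage"``.
    message:
        Human-readable description of the violation.
    """

    def __init__(self, path: str, message: str) -> None:
        self.path = path
        self.message = message
        super().__init__(f"{path}: {message}")


class TerminologyError(AdheremonError):
    """A concept code cannot be resolved against the code map."""


class UnitError(AdheremonError):
    """Two quantities carry units that cannot be converted into each other."""


class DataFormatError(AdheremonError):
    """A clinical-data CSV file is missing, malformed, or invalid."""


class CohortValidationError(DataFormatError):
    """A loaded cohort violates the common-data-model invariants.

    Carries the full list of error findings in :attr:`findings`.
    """

    def __init__(self, findings) -> None:
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in self.findings[:10])
        more = "" if len(self.findings) <= 10 else f" (+{len(self.findings) - 10} more)"
        super().__init__(f"cohort validation failed: {lines}{more}")


class EvaluationError(AdheremonError):
    """Evaluation cannot proceed (unknown person, invalid window, ...)."""
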