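"""Unit-of-measure handling for the UCUM subset the engine supports.

The engine deliberately supports a small, fixed subset of UCUM rather than a
full UCUM grammar: the mass units used for drug doses (``ug``, ``mg``,
``g``), dimensionless percent (``%``), and the time units used in dosing
schedules (``h``, ``d``).  Conversion is only defined within a dimension
group; converting e.g. ``mg`` to ``%`` raises :class:`~adheremon.errors.UnitError`.
"""

from __future__ import annotations

from .errors import UnitError

#: Conversion factors to each group's base unit (mg for mass, h for time).
UNIT_GROUPS: dict[str, dict[str, float]] = {
    "mass": {"ug": 1e-3, "mg": 1.0, "g": 1e3},
    "percent": {"%": 1.0},
    "time": {"h": 1.0, "d": 24.0},
}

#: All supported UCUM codes.
SUPPORTED_UNITS: frozenset[str] = frozenset(
    code for group in UNIT_GROUPS.values() for code in group
)

_GROUP_OF: dict[str, str] = {
    code: name for name, group in UNIT_GROUPS.items() for code in group
}


def unit_group(code: str) -> str:
    """Return the dimension group of a UCUM code; raise for unsupported codes."""
    try:
        return _GROUP_OF[code]
    except KeyError:
        raise UnitError(f"unsupported UCUM unit {code!r}") from None


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` from ``from_unit`` to ``to_unit``.

    Raises
    ------
    UnitError
        If either unit is unsupported or the units belong to different
        dimension groups (e.g. mass vs percent).
    """
    if from_unit == to_unit:
        return float(value)
    g_from, g_to = unit_group(from_unit), unit_group(to_unit)
    if g_from != g_to:
        raise UnitError(
            f"incomparable units: {from_unit!r} ({g_from}) vs {to_unit!r} ({g_to})"
        )
    table = UNIT_GROUPS[g_from]
    return float(value) * table[from_unit] / table[to_unit]
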