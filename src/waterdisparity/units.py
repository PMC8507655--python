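"""Concentration unit handling.

Mass concentrations (ng/L, µg/L, mg/L) interconvert by powers of 1000.
Radiological activity (pCi/L) is its own dimension: converting between
activity and mass units for a single contaminant is a data error, not a
missing conversion factor.
"""

from __future__ import annotations

__all__ = ["canonical_unit", "convert", "UnitError"]


class UnitError(ValueError):
    """Raised for unrecognized units or mass/activity mixing."""


# factors to µg/L within the mass dimension
_MASS_FACTORS = {
    "ng/L": 1e-3,
    "ug/L": 1.0,
    "µg/L": 1.0,
    "mg/L": 1e3,
}
_ACTIVITY_UNITS = {"pCi/L"}


def canonical_unit(unit: str) -> str:
    """Normalize spelling (``ug/L`` → ``µg/L``); raise on unknown units."""
    u = unit.strip()
    if u in ("ug/L", "µg/L", "µg/L", "μg/L"):
        return "µg/L"
    if u in _MASS_FACTORS or u in _ACTIVITY_UNITS:
        return u
    raise UnitError(f"unrecognized concentration unit: {unit!r}")


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between recognized units.

    Raises :class:`UnitError` if either unit is unknown or the conversion
    crosses the mass/activity boundary.
    """
    fu, tu = canonical_unit(from_unit), canonical_unit(to_unit)
    if fu == tu:
        return value
    if fu in _ACTIVITY_UNITS or tu in _ACTIVITY_UNITS:
        raise UnitError(
            f"cannot convert between activity and mass units ({from_unit} → {to_unit})"
        )
    return value * _MASS_FACTORS[fu] / _MASS_FACTORS[tu]
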