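"""Unit registry and conversions.

Canonical internal units are mm / ms / kPa / mL, chosen so the printed
myocardial conductivities (mm^2/ms) and tissue pressures (kPa) are near
unity.  The lumped afterload keeps its native clinical units (mmHg, s, mL)
and is converted at the coupling boundary.
"""

from __future__ import annotations

# 1 mmHg in kPa (101.325 kPa / 760 mmHg)
MMHG_TO_KPA = 0.133322
KPA_TO_MMHG = 1.0 / MMHG_TO_KPA

#: multiplicative factor taking *unit* into the canonical unit of its quantity
_FACTORS = {
    # length -> mm
    "mm": 1.0,
    "cm": 10.0,
    "m": 1000.0,
    # time -> ms
    "ms": 1.0,
    "s": 1000.0,
    # pressure -> kPa
    "kPa": 1.0,
    "Pa": 1e-3,
    "MPa": 1e3,
    "mmHg": MMHG_TO_KPA,
    # volume -> mL
    "mL": 1.0,
    "uL": 1e-3,
    "mm3": 1e-3,
    "L": 1e3,
    # angles -> deg
    "deg": 1.0,
}


class UnitError(ValueError):
    pass


def to_canonical(value: float, unit: str) -> float:
    """Convert *value* carrying *unit* into the canonical unit of its quantity."""
    try:
        return value * _FACTORS[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}; known: {sorted(_FACTORS)}") from None


def from_canonical(value: float, unit: str) -> float:
    try:
        return value / _FACTORS[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}; known: {sorted(_FACTORS)}") from None


def parse_quantity(spec) -> float:
    """Parse ``3.2``, ``"3.2"`` or ``"3.2 mmHg"`` into a canonical-unit float."""
    if isinstance(spec, (int, float)):
        return float(spec)
    parts = str(spec).split()
    if len(parts) == 1:
        return float(parts[0])
    if len(parts) == 2:
        return to_canonical(float(parts[0]), parts[1])
    raise UnitError(f"cannot parse quantity {spec!r}")
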