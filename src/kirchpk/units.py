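"""Unit handling.

Canonical units throughout the package are hours, liters and L/h.
Renal physiology is conventionally quoted in mL/min (1 L/h = 1000/60
mL/min ≈ 16.667 mL/min); constructors accept explicitly tagged mL/min
values and convert on the way in.
"""

from __future__ import annotations

ML_MIN_PER_L_H = 1000.0 / 60.0  # exactly 16.666...

RATE_UNITS = ("1/h",)
CLEARANCE_UNITS = ("L/h", "mL/min")
KNOWN_UNITS = RATE_UNITS + CLEARANCE_UNITS


def ml_min_to_l_h(value: float) -> float:
    """Convert a flow/clearance from mL/min to L/h."""
    return value / ML_MIN_PER_L_H


def l_h_to_ml_min(value: float) -> float:
    """Convert a flow/clearance from L/h to mL/min."""
    return value * ML_MIN_PER_L_H


def to_canonical(value: float, units: str) -> float:
    """Convert a tagged magnitude to canonical units (1/h or L/h)."""
    if units in ("1/h", "L/h"):
        return value
    if units == "mL/min":
        return ml_min_to_l_h(value)
    raise ValueError(f"unknown units {units!r}; expected one of {KNOWN_UNITS}")


def kind_of_units(units: str) -> str:
    """Map a unit tag to the process kind it implies."""
    if units in RATE_UNITS:
        return "rate_constant"
    if units in CLEARANCE_UNITS:
        return "clearance"
    raise ValueError(f"unknown units {units!r}; expected one of {KNOWN_UNITS}")
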