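"""Concentration unit handling.

All concentrations are carried internally in molar; CSV inputs declare
their unit per row (``concentration_unit`` / ``conc_unit`` columns) and are
converted on read.
"""

from __future__ import annotations

_FACTORS = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,  # greek mu vs micro sign
    "nm": 1e-9,
    "pm": 1e-12,
}


def to_molar(value: float, unit: str) -> float:
    """Convert a concentration in ``unit`` to molar.

    Accepted units: M, mM, uM/µM, nM, pM (case-insensitive).
    """
    try:
        return value * _FACTORS[unit.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def from_molar(value: float, unit: str) -> float:
    """Convert a molar concentration to ``unit``."""
    try:
        return value / _FACTORS[unit.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None
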