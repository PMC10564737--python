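"""Thermodynamic, reactivity and mass arithmetic for ligand characterization.

* Binding free energy dG = RT ln(K_D / 1 M) in kcal/mol, the enthalpy/
  entropy split -TdS = dG - dH, and ligand efficiency
  LE = -RT ln(K_D)/NHA (kcal/mol per non-hydrogen atom).
* Glutathione-reactivity half-life: an electrophile incubated with excess
  GSH decays pseudo-first-order, C(t) = C0 exp(-k_e t), T_1/2 = ln2/k_e.
  (Instrument software sometimes prints the rate with a negative sign;
  here k_e > 0 denotes decay.)
* Elemental-composition arithmetic in the MaxQuant modification dialect
  ("C(26)H(25)N(3)O(7)FPSe(-1)S": element symbol, optional signed count in
  parentheses, bare symbol = 1; negative counts encode placeholder
  corrections). Monoisotopic and average masses come from the NIST atomic
  mass table bundled with pyteomics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass
from scipy.optimize import curve_fit

from .binding import FitError

__all__ = [
    "R_KCAL",
    "ThermoRecord",
    "Composition",
    "DecayFit",
    "delta_g",
    "entropy_term",
    "ligand_efficiency",
    "fit_gsh_decay",
    "parse_composition",
    "composition_mass",
    "covalent_adduct_composition",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.98720425e-3

#: Default temperature (K) for dG/LE arithmetic (calorimetry temperature).
T_DEFAULT = 298.0

MASS_TABLE_PROVENANCE = "pyteomics.mass.nist_mass (NIST atomic masses)"


def delta_g(K_D: float, T: float = T_DEFAULT) -> float:
    """Binding free energy dG = RT ln(K_D/1M), kcal/mol (standard state 1 M)."""
    if K_D <= 0 or T <= 0:
        raise ValueError("K_D and T must be > 0")
    return R_KCAL * T * math.log(K_D)


def entropy_term(dG: float, dH: float) -> float:
    """-T dS = dG - dH (kcal/mol), from the identity dG = dH - T dS."""
    if not (math.isfinite(dG) and math.isfinite(dH)):
        raise ValueError("dG and dH must be finite")
    return dG - dH


def ligand_efficiency(K_D: float, NHA: int, T: float = T_DEFAULT) -> float:
    """Ligand efficiency LE = -RT ln(K_D)/NHA, kcal/mol per heavy atom."""
    if NHA < 1:
        raise ValueError("NHA must be >= 1")
    return -delta_g(K_D, T) / NHA


@dataclass
class ThermoRecord:
    """Self-consistent thermodynamic summary of one ligand.

    dG and LE are derived from K_D at temperature T; -TdS from dH when a
    calorimetric enthalpy is supplied. The internal identities
    (dG = RT ln K_D, minusTdS = dG - dH, LE = -dG/NHA) hold to 1e-9 by
    construction.
    """

    K_D: float
    NHA: int
    T: float = T_DEFAULT
    dH: float | None = None
    dG: float = field(init=False)
    minusTdS: float | None = field(init=False)
    LE: float = field(init=False)

    def __post_init__(self):
        self.dG = delta_g(self.K_D, self.T)
        self.minusTdS = entropy_term(self.dG, self.dH) if self.dH is not None else None
        self.LE = ligand_efficiency(self.K_D, self.NHA, self.T)


@dataclass
class DecayFit:
    """Pseudo-first-order decay fit: C(t) = C0 exp(-k_e t)."""

    C0: float
    k_e: float  # per minute, > 0 for decay
    T_half: float  # minutes; inf for a non-reactive compound
    standard_errors: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def fit_gsh_decay(times_min, responses) -> DecayFit:
    """Fit a GSH-reactivity time course to C(t) = C0 exp(-k_e t).

    times are minutes; responses are analyte/internal-standard peak-area
    ratios. Percent remaining is defined relative to the fitted C0 (time
    zero). An increasing series is flagged non-reactive with
    T_half = +inf. T_half * k_e = ln 2 exactly by construction.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(responses, dtype=float)
    if t.size < 4:
        raise FitError("need at least 4 time points")
    if t.shape != y.shape:
        raise ValueError("times and responses must have equal length")
    slope = np.polyfit(t, y, 1)[0]
    if slope >= 0:
        return DecayFit(C0=float(np.mean(y)), k_e=0.0, T_half=math.inf,
                        flags={"non_reactive": True})

    def model(t, C0, k):
        return C0 * np.exp(-k * t)

    k0 = max(-slope / max(y[0], 1e-12), 1e-6)
    popt, pcov = curve_fit(model, t, y, p0=[y[0], k0],
                           bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
    C0, k_e = map(float, popt)
    if k_e == 0:
        return DecayFit(C0=C0, k_e=0.0, T_half=math.inf,
                        flags={"non_reactive": True})
    se = np.sqrt(np.diag(pcov))
    return DecayFit(
        C0=C0, k_e=k_e, T_half=math.log(2.0) / k_e,
        standard_errors={"C0": float(se[0]), "k_e": float(se[1])},
    )


@dataclass(frozen=True)
class Composition:
    """Signed element-count map (e.g. a modification composition)."""

    element_counts: tuple  # sorted tuple of (symbol, count)

    @classmethod
    def from_dict(cls, counts: dict) -> "Composition":
        # zero counts cancel out; an all-zero map is the empty composition
        # (the identity for composition arithmetic)
        clean = {el: int(n) for el, n in counts.items() if n != 0}
        for el in clean:
            if el not in _pmass.nist_mass:
                raise ValueError(f"unknown element symbol {el!r}")
        return cls(tuple(sorted(clean.items())))

    def as_dict(self) -> dict:
        return dict(self.element_counts)

    def __add__(self, other: "Composition") -> "Composition":
        counts = self.as_dict()
        for el, n in other.element_counts:
            counts[el] = counts.get(el, 0) + n
        return Composition.from_dict(counts)

    def __sub__(self, other: "Composition") -> "Composition":
        counts = self.as_dict()
        for el, n in other.element_counts:
            counts[el] = counts.get(el, 0) - n
        return Composition.from_dict(counts)

    def serialize(self) -> str:
        """Canonical string in the parenthesized-count dialect (Hill-ish order)."""
        parts = []
        for el, n in self.element_counts:
            parts.append(el if n == 1 else f"{el}({n})")
        return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(?:\((-?\d+)\))?")


def parse_composition(text: str) -> Composition:
    """Parse a MaxQuant-style composition string.

    Grammar: one or more tokens, each an element symbol optionally
    followed by a signed integer count in parentheses; a bare symbol means
    count 1. Example: ``C(26)H(25)N(3)O(7)FPSe(-1)S``.

    Raises
    ------
    ValueError
        On malformed text or unknown element symbols, with the offending
        position in the message.
    """
    if not text or not text.strip():
        raise ValueError("empty composition string")
    s = text.strip()
    counts: dict = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None:
            raise ValueError(f"malformed composition at position {pos}: {s[pos:]!r}")
        el, n = m.group(1), m.group(2)
        if el not in _pmass.nist_mass:
            raise ValueError(f"unknown element symbol {el!r} at position {pos}")
        counts[el] = counts.get(el, 0) + (int(n) if n is not None else 1)
        pos = m.end()
    return Composition.from_dict(counts)


def _average_mass(element: str) -> float:
    isotopes = _pmass.nist_mass[element]
    avg = sum(m * ab for iso, (m, ab) in isotopes.items() if iso != 0)
    return avg if avg > 0 else isotopes[0][0]  # elements with no abundances


def composition_mass(c: Composition, kind: str = "monoisotopic") -> float:
    """Signed mass of a composition in daltons.

    kind: "monoisotopic" (principal isotope masses) or "average"
    (abundance-weighted standard atomic weights). Masses are the NIST
    values shipped with pyteomics; additive over composition arithmetic.
    """
    if kind == "monoisotopic":
        return float(sum(n * _pmass.nist_mass[el][0][0]
                         for el, n in c.element_counts))
    if kind == "average":
        return float(sum(n * _average_mass(el) for el, n in c.element_counts))
    raise ValueError("kind must be 'monoisotopic' or 'average'")


def covalent_adduct_composition(ligand: Composition, leaving_group: Composition) -> Composition:
    """Composition of the covalent adduct: ligand minus leaving group.

    For a chloroacetamide warhead reacting with a cysteine thiol, the
    leaving group is HCl and the adduct is the thioether-linked remainder.
    Subtraction that would require an element absent from the ligand is an
    error.
    """
    lig = ligand.as_dict()
    for el, n in leaving_group.element_counts:
        if lig.get(el, 0) < n:
            raise ValueError(
                f"leaving group requires {n} x {el} but ligand has {lig.get(el, 0)}"
            )
    return ligand - leaving_group
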