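"""Elemental masses, formula handling and adduct arithmetic.

Monoisotopic masses are CODATA/IUPAC values for the lightest isotope of each
element.  All m/z arithmetic assumes singly charged ions; the electron mass
is neglected (<1 ppm below m/z 1,200).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Monoisotopic masses of the elements occurring in lipid sum formulas (Da).
ELEMENT_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Mass difference between 13C and 12C (Da); used for the M+1 isotopologue.
C13_DELTA = 1.0033548378

#: Natural abundance ratio 13C/12C; expected M+1/M intensity is this per carbon.
C13_ABUNDANCE = 0.0107

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula string like ``C42H80NO8P`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        elem, num = match.group(1), match.group(2)
        if elem not in ELEMENT_MASS:
            raise ValueError(f"unknown element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Hill-order string (C, H, then alphabetical) for an element-count map."""
    parts = []
    for elem in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
        n = counts.get(elem, 0)
        if n > 0:
            parts.append(elem + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: dict[str, int] | str) -> float:
    """Monoisotopic (lightest-isotope) mass of a formula, in Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ELEMENT_MASS[e] * n for e, n in counts.items())


@dataclass(frozen=True)
class AdductRule:
    """An ionisation adduct: neutral M observed at ``M + mass_shift`` (z=1)."""

    name: str
    mode: str  # "positive" | "negative"
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mode == "positive" and self.mass_shift < 0:
            raise ValueError(f"{self.name}: negative shift in positive mode")
        if self.mode == "negative" and self.mass_shift > 0:
            raise ValueError(f"{self.name}: positive shift in negative mode")


#: The five adducts handled throughout the package.  Shifts are the proton /
#: sodium / ammonium / potassium monoisotopic masses (proton-bound values).
ADDUCTS: dict[str, AdductRule] = {
    "[M+H]+": AdductRule("[M+H]+", "positive", +1.007276),
    "[M+Na]+": AdductRule("[M+Na]+", "positive", +22.989218),
    "[M+NH4]+": AdductRule("[M+NH4]+", "positive", +18.033823),
    "[M+K]+": AdductRule("[M+K]+", "positive", +38.963158),
    "[M-H]-": AdductRule("[M-H]-", "negative", -1.007276),
}


def theoretical_mz(monoisotopic: float, adduct: AdductRule) -> float:
    """m/z of the singly charged adduct ion of a neutral of given mass."""
    if monoisotopic <= 0:
        raise ValueError("monoisotopic mass must be positive")
    return monoisotopic + adduct.mass_shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, (obs − theo)/theo × 1e6 (ppm)."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
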