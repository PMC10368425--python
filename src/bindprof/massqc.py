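"""Mass-shift arithmetic for intact-protein QC.

Deconvoluted intact-protein masses from native MS are average (not
monoisotopic) masses, so the default mode sums standard atomic weights
(IUPAC 2021 abridged values); monoisotopic masses are available behind a
flag. Typical uses: the myristoyl modification C14H26O (210.4 Da,
explaining a ~211 Da intact-mass increase of the myristoylated protein)
and the ~40 Da shift upon binding of a single Ca2+ ion.

The calcium shift is reported as the neutral-atom mass (40.08 Da). With
charge compensation (Ca minus 2H, 38.06 Da) the expected shift would be
~38 Da; both lie within the ~+/-1 Da accuracy of intact-mass
measurements, which cannot distinguish the two.
"""

from __future__ import annotations

import re

__all__ = ["parse_formula", "average_mass", "delta_mass", "ATOMIC_WEIGHTS", "MONOISOTOPIC_MASSES"]

# IUPAC 2021 abridged standard atomic weights (Da)
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "Mg": 24.305,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
    "Se": 78.971,
}

# lightest-isotope exact masses (Da)
MONOISOTOPIC_MASSES = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "Mg": 23.9850417,
    "Cl": 34.96885271,
    "K": 38.96370649,
    "Ca": 39.9625912,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
    "Se": 79.9165218,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    """Parse a Hill-notation elemental formula, e.g. ``"C14H26O"``.

    Returns a mapping element -> count; repeated elements accumulate.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element = m.group(1)
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def average_mass(formula: dict | str, monoisotopic: bool = False) -> float:
    """Molecular mass (Da) of an elemental formula.

    Average atomic weights by default; exact lightest-isotope masses
    with ``monoisotopic=True``. The empty formula has mass 0.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    table = MONOISOTOPIC_MASSES if monoisotopic else ATOMIC_WEIGHTS
    total = 0.0
    for element, count in formula.items():
        if element not in table:
            raise ValueError(f"unknown element {element!r}")
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        total += table[element] * count
    return total


def delta_mass(m1: float, m2: float) -> float:
    """Absolute difference |m1 - m2| between two masses (Da)."""
    if m1 < 0 or m2 < 0:
        raise ValueError("masses must be non-negative")
    return abs(m1 - m2)
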