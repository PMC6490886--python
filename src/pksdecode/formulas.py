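"""Elemental formula bookkeeping and monoisotopic masses.

Formulas are plain ``dict[str, int]`` element->count maps.  Only the elements
that occur in polyketide/deoxysugar chemistry are tabulated; masses are CODATA
2018-era monoisotopic values, sufficient for the 1e-4 Da agreement the product
module promises.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

#: Monoisotopic masses of the principal isotope, in Da.
MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Mass of a proton (for [M+H]+ adducts), Da.
PROTON_MASS: float = 1.00727646688

WATER: dict[str, int] = {"H": 2, "O": 1}


def add(*formulas: Mapping[str, int]) -> dict[str, int]:
    """Sum formulas elementwise, dropping zero counts."""
    total: Counter[str] = Counter()
    for f in formulas:
        total.update(f)
    return {el: n for el, n in sorted(total.items()) if n != 0}


def subtract(a: Mapping[str, int], b: Mapping[str, int]) -> dict[str, int]:
    neg = {el: -n for el, n in b.items()}
    return add(a, neg)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da; raises KeyError on untabulated elements."""
    if any(n < 0 for n in formula.values()):
        raise ValueError(f"negative element count in formula: {dict(formula)}")
    return sum(MONOISOTOPIC[el] * n for el, n in formula.items())


def hill_notation(formula: Mapping[str, int]) -> str:
    """Hill-convention string (C first, H second, then alphabetical)."""
    parts = []
    rest = dict(formula)
    for el in ("C", "H"):
        n = rest.pop(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    for el in sorted(rest):
        n = rest[el]
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)
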