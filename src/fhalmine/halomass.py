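"""Monoisotopic mass and halogen isotopologue utilities.

The computational counterpart of a GC-MS check on halogenated products:
given a molecular formula, compute the neutral monoisotopic mass for a
chosen halogen isotope assignment, and predict the characteristic
chlorine/bromine isotopologue doublet/multiplet pattern (e.g. the
near-1:1 79Br/81Br doublet of 3-bromoindole, C8H6BrN: 194.968 and
196.966 Da, split by 1.998 Da).

Masses are neutral-molecule sums (no proton or electron adjustment),
computed from an embedded isotope table; displayed values round half-up
to three decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import product
from math import comb

# Monoisotopic isotope masses (Da) and natural abundances.  Most-abundant
# isotope first per element; values from the standard NIST atomic-mass
# compilation, truncated to the precision used in small-molecule MS.
ISOTOPES: dict[str, list[tuple[int, float, float]]] = {
    # element: [(nominal, mass, abundance), ...]
    "H": [(1, 1.00782503, 0.999885), (2, 2.01410178, 0.000115)],
    "C": [(12, 12.0, 0.9893), (13, 13.00335484, 0.0107)],
    "N": [(14, 14.00307401, 0.99636), (15, 15.00010890, 0.00364)],
    "O": [(16, 15.99491462, 0.99757), (18, 17.99915961, 0.00205)],
    "S": [(32, 31.97207117, 0.9499), (34, 33.96786690, 0.0425)],
    "P": [(31, 30.97376163, 1.0)],
    "F": [(19, 18.99840322, 1.0)],
    "I": [(127, 126.90447300, 1.0)],
    "Cl": [(35, 34.96885268, 0.7576), (37, 36.96590259, 0.2424)],
    "Br": [(79, 78.91833710, 0.5069), (81, 80.91629060, 0.4931)],
}

HALOGENS = ("Cl", "Br")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class IsotopologuePeak:
    mass: float
    rel_abundance: float


MolecularFormula = dict[str, int]


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string like 'C8H6BrN' into an
    element->count map."""
    formula: MolecularFormula = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        if not m.group(0):
            break
        elem = m.group(1)
        if elem not in ISOTOPES:
            raise ValueError(f"unknown element {elem!r} in formula {text!r}")
        count = int(m.group(2)) if m.group(2) else 1
        formula[elem] = formula.get(elem, 0) + count
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return formula


def _isotope_mass(element: str, nominal: int | None = None) -> float:
    if element not in ISOTOPES:
        raise ValueError(f"unknown element {element!r}")
    entries = ISOTOPES[element]
    if nominal is None:
        return entries[0][1]  # most abundant
    for nom, mass, _ in entries:
        if nom == nominal:
            return mass
    raise ValueError(f"no isotope {nominal} of element {element!r} in table")


def monoisotopic_mass(
    formula: MolecularFormula | str,
    halogen_isotopes: dict[str, int] | None = None,
) -> float:
    """Neutral monoisotopic mass for a specific isotope assignment.

    Non-halogen elements use their most abundant isotope; halogens may be
    pinned via halogen_isotopes, e.g. {'Br': 79} or {'Br': 81}.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    halogen_isotopes = halogen_isotopes or {}
    total = 0.0
    for elem, count in formula.items():
        if count < 0:
            raise ValueError(f"negative count for element {elem!r}")
        total += count * _isotope_mass(elem, halogen_isotopes.get(elem))
    return total


def display_mass(mass: float, places: int = 3) -> float:
    """Round half-up for display (the convention of printed MS tables)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(mass)).quantize(q, rounding=ROUND_HALF_UP))


def halogen_pattern(formula: MolecularFormula | str) -> list[IsotopologuePeak]:
    """Predicted Cl/Br isotopologue peaks, sorted by mass.

    Every combination of light/heavy chlorine and bromine assignments is
    enumerated with binomial weights from the natural abundances;
    non-halogen elements stay monoisotopic.  Abundances sum to 1; peaks
    within 1e-6 Da are merged.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    base_formula = {e: c for e, c in formula.items() if e not in HALOGENS}
    base = monoisotopic_mass(base_formula)
    per_halogen: list[list[tuple[float, float]]] = []
    for hal in HALOGENS:
        n = formula.get(hal, 0)
        if n == 0:
            continue
        (_, m_light, p_light), (_, m_heavy, p_heavy) = ISOTOPES[hal]
        opts = []
        for k in range(n + 1):  # k heavy atoms among n
            mass = (n - k) * m_light + k * m_heavy
            ab = comb(n, k) * (p_light ** (n - k)) * (p_heavy ** k)
            opts.append((mass, ab))
        # natural-abundance pair does not sum to exactly 1; renormalize
        tot = sum(a for _, a in opts)
        per_halogen.append([(m, a / tot) for m, a in opts])
    if not per_halogen:
        return [IsotopologuePeak(base, 1.0)]
    peaks: dict[float, float] = {}
    for combo in product(*per_halogen):
        mass = base + sum(m for m, _ in combo)
        ab = 1.0
        for _, a in combo:
            ab *= a
        key = round(mass, 6)
        peaks[key] = peaks.get(key, 0.0) + ab
    return [IsotopologuePeak(m, peaks[m]) for m in sorted(peaks)]
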