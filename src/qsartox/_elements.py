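"""Element data for descriptor computation.

Standard atomic weights (IUPAC), valence-electron counts Z_v, atomic numbers
Z, principal quantum numbers L, and Kier alpha covalent-radius ratios
relative to sp3 carbon (r = 0.77 A).  Only elements that occur in the
organic aromatic chemistry this package targets are listed; anything else is
rejected at parse time.
"""

from __future__ import annotations

#: supported heavy elements (H handled implicitly)
SUPPORTED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)

ATOMIC_MASS = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.01,
    "N": 14.01,
    "O": 16.00,
    "F": 19.00,
    "Si": 28.09,
    "P": 30.97,
    "S": 32.07,
    "Cl": 35.45,
    "Br": 79.90,
    "I": 126.90,
}

ATOMIC_NUMBER = {
    "H": 1,
    "B": 5,
    "C": 6,
    "N": 7,
    "O": 8,
    "F": 9,
    "Si": 14,
    "P": 15,
    "S": 16,
    "Cl": 17,
    "Br": 35,
    "I": 53,
}

VALENCE_ELECTRONS = {
    "H": 1,
    "B": 3,
    "C": 4,
    "N": 5,
    "O": 6,
    "F": 7,
    "Si": 4,
    "P": 5,
    "S": 6,
    "Cl": 7,
    "Br": 7,
    "I": 7,
}

#: principal quantum number of the valence shell
PRINCIPAL_QUANTUM = {
    "H": 1,
    "B": 2,
    "C": 2,
    "N": 2,
    "O": 2,
    "F": 2,
    "Si": 3,
    "P": 3,
    "S": 3,
    "Cl": 3,
    "Br": 4,
    "I": 5,
}

#: covalent radii (Angstrom) by (element, hybridization); hybridization is
#: 'sp3', 'sp2' or 'sp', inferred from bond orders
COVALENT_RADIUS = {
    ("C", "sp3"): 0.77,
    ("C", "sp2"): 0.67,
    ("C", "sp"): 0.60,
    ("N", "sp3"): 0.74,
    ("N", "sp2"): 0.62,
    ("N", "sp"): 0.55,
    ("O", "sp3"): 0.74,
    ("O", "sp2"): 0.62,
    ("F", "sp3"): 0.72,
    ("Cl", "sp3"): 0.99,
    ("Br", "sp3"): 1.14,
    ("I", "sp3"): 1.33,
    ("S", "sp3"): 1.04,
    ("S", "sp2"): 0.94,
    ("P", "sp3"): 1.10,
    ("P", "sp2"): 1.00,
    ("B", "sp3"): 0.88,
    ("B", "sp2"): 0.80,
    ("Si", "sp3"): 1.17,
}

_R_CSP3 = COVALENT_RADIUS[("C", "sp3")]


def kier_alpha(symbol: str, hybridization: str) -> float:
    """Kier alpha contribution r_x / r(Csp3) - 1 for one heavy atom."""
    r = COVALENT_RADIUS.get((symbol, hybridization))
    if r is None:
        r = COVALENT_RADIUS.get((symbol, "sp3"))
    if r is None:
        raise KeyError(f"no covalent radius for element {symbol!r}")
    return r / _R_CSP3 - 1.0
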