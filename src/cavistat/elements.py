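"""Bundled element tables: atomic weights and van der Waals radii.

Atomic weights are the IUPAC 2021 conventional values to four decimals,
sufficient to reproduce tabulated solvent molar masses to two decimals.
Van der Waals radii default to the Bondi set for the elements that occur
in proteins and small organic solvents.
"""

from __future__ import annotations

# IUPAC 2021 conventional atomic weights, g/mol (4 decimals where defined)
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.9984,
    "Na": 22.9898,
    "Mg": 24.305,
    "P": 30.9738,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.0983,
    "Ca": 40.078,
    "Mn": 54.938,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Se": 78.971,
    "Br": 79.904,
    "I": 126.9045,
}

# Bondi vdW radii, Å. "default" is the set used throughout unless overridden.
VDW_RADII: dict[str, dict[str, float]] = {
    "default": {
        "H": 1.20,
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "F": 1.47,
        "P": 1.80,
        "S": 1.80,
        "Cl": 1.75,
        "Br": 1.85,
        "I": 1.98,
    },
}


def atomic_weight(element: str) -> float:
    """Atomic weight of an element symbol (case-normalised)."""
    sym = element.capitalize()
    try:
        return ATOMIC_WEIGHTS[sym]
    except KeyError:
        raise KeyError(f"element {element!r} not in bundled atomic-weight table") from None


def vdw_radius(element: str, radius_set: str = "default", default: float | None = None) -> float:
    """Van der Waals radius in Å from the named bundled set.

    Falls back to ``default`` if the element is absent from the table;
    raises if the element is unknown and no fallback is supplied.
    """
    try:
        table = VDW_RADII[radius_set]
    except KeyError:
        raise KeyError(f"unknown radius set {radius_set!r}; available: {sorted(VDW_RADII)}") from None
    sym = element.capitalize()
    if sym in table:
        return table[sym]
    if default is not None:
        return float(default)
    raise KeyError(
        f"element {element!r} not in radius set {radius_set!r} and no default radius supplied"
    )


def is_known_element(symbol: str) -> bool:
    return symbol.capitalize() in ATOMIC_WEIGHTS
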