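"""Formula arithmetic and solvent-space metrics for bio-based solvent screening.

Xylose acetals (DFX, DPX, DBX, DIBX) are made by condensing D-xylose
(C5H10O5) with two equivalents of an aldehyde, releasing two waters:

    product = sugar + n·aldehyde − n·H₂O        (n = 2 cyclic acetals)

Each acetal substitutes two of the sugar's hydrogens, so a di-acetal
replaces four; on a mass basis ~97 % of the xylose survives into the
solvent. This module implements that stoichiometry, molar masses from
the bundled atomic-weight table, biomass-utilisation efficiency, and
two solvent-similarity metrics: the Hansen solubility-parameter
distance Ra² = 4ΔδD² + ΔδP² + ΔδH² and nearest neighbours in the
Kamlet–Abboud–Taft (π*, β) plane.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .elements import ATOMIC_WEIGHTS, atomic_weight

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

XYLOSE = None  # set below once Formula exists
WATER = None
XYLAN_UNIT = None  # anhydroxylose repeat unit of xylan


@dataclass(frozen=True)
class Formula:
    """Element→count map with element-wise arithmetic."""

    counts: tuple[tuple[str, int], ...]

    @staticmethod
    def from_dict(d: dict[str, int]) -> "Formula":
        items = {k.capitalize(): int(v) for k, v in d.items() if int(v) != 0}
        if not items:
            raise ValueError("formula must contain at least one element")
        if any(v < 0 for v in items.values()):
            raise ValueError("element counts must be non-negative")
        return Formula(tuple(sorted(items.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def count(self, element: str) -> int:
        return self.as_dict().get(element.capitalize(), 0)

    def __add__(self, other: "Formula") -> "Formula":
        c = Counter(self.as_dict())
        c.update(other.as_dict())
        return Formula.from_dict(dict(c))

    def scale(self, n: int) -> "Formula":
        return Formula.from_dict({k: v * n for k, v in self.counts})

    def subtract(self, other: "Formula") -> "Formula":
        c = Counter(self.as_dict())
        c.subtract(other.as_dict())
        if any(v < 0 for v in c.values()):
            raise ValueError(f"subtraction gives negative counts: {dict(c)}")
        return Formula.from_dict({k: v for k, v in c.items() if v})

    def hill(self) -> str:
        """Hill-notation string (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        for el in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            if el in d:
                parts.append(el + (str(d[el]) if d[el] != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula such as ``C7H10O5``."""
    text = text.strip()
    pos = 0
    counts: Counter[str] = Counter()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(f"invalid formula {text!r} at position {pos}")
        el = m.group(1)
        if el not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {el!r} in formula {text!r}")
        counts[el] += int(m.group(2)) if m.group(2) else 1
        pos = m.end()
    if not counts:
        raise ValueError(f"empty formula {text!r}")
    return Formula.from_dict(dict(counts))


def molecular_weight(formula: Formula) -> float:
    """Σ count × atomic weight, g/mol (full precision; round for display)."""
    return sum(n * atomic_weight(el) for el, n in formula.counts)


XYLOSE = parse_formula("C5H10O5")
WATER = parse_formula("H2O")
XYLAN_UNIT = parse_formula("C5H8O4")


# ---------------------------------------------------------------------------
# acetalisation stoichiometry
# ---------------------------------------------------------------------------


def acetal_product(sugar: Formula, aldehyde: Formula, n_acetals: int = 2) -> Formula:
    """Product of acetalising a sugar with n aldehydes: sugar + n·ald − n·H₂O."""
    if n_acetals < 1:
        raise ValueError("n_acetals must be ≥ 1")
    return (sugar + aldehyde.scale(n_acetals)).subtract(WATER.scale(n_acetals))


def substituted_hydrogens(sugar: Formula, product: Formula, n_acetals: int = 2) -> int:
    """Sugar hydrogens replaced on forming the acetal product.

    The aldehyde is inferred from the stoichiometry
    ``aldehyde = (product − sugar + n·H₂O) / n``; a non-integral or
    negative inference means the product did not come from this sugar
    by acetalisation and raises. For a valid n-acetal the answer is
    2·n (each cyclic acetal consumes two hydroxyl hydrogens).
    """
    diff = (product + WATER.scale(n_acetals)).subtract(sugar).as_dict()
    if any(v % n_acetals for v in diff.values()):
        raise ValueError("inconsistent stoichiometry: aldehyde counts are not integral")
    aldehyde = {k: v // n_acetals for k, v in diff.items()}
    n_sub = sugar.count("H") - (product.count("H") - n_acetals * aldehyde.get("H", 0))
    if n_sub != 2 * n_acetals:
        raise ValueError(f"inconsistent stoichiometry: {n_sub} ≠ 2×{n_acetals} hydrogens")
    return n_sub


def retention_fraction(sugar: Formula, n_h_substituted: int) -> float:
    """Mass fraction of the sugar retained in the product.

    (MW(sugar) − n × MW(H)) / MW(sugar): the sugar core minus the
    substituted hydrogens, on a mass basis. For xylose with the four
    hydrogens a di-acetal replaces, this is 0.973 → "97 %".
    """
    if n_h_substituted < 0:
        raise ValueError("n_h_substituted must be ≥ 0")
    if n_h_substituted > sugar.count("H"):
        raise ValueError(
            f"cannot substitute {n_h_substituted} H from a sugar with {sugar.count('H')}"
        )
    mw = molecular_weight(sugar)
    return (mw - n_h_substituted * atomic_weight("H")) / mw


@dataclass
class EfficiencyResult:
    """Biomass utilisation efficiency, stoichiometric and actual."""

    stoichiometric_fraction: float
    actual_fraction: float
    basis: str  # "xylose" or "xylan_unit"


def utilization_efficiency(
    retained: Formula,
    basis_unit: Formula = XYLAN_UNIT,
    yield_mol_fraction: float = 1.0,
    basis: str = "xylan_unit",
) -> EfficiencyResult:
    """Fraction of the feedstock mass that ends up in the product.

    ``stoichiometric = MW(retained) / MW(basis_unit)`` is the theoretical
    ceiling (all of the retained fragment from every basis unit);
    ``actual = stoichiometric × yield``. ``retained`` must be an
    element-wise subset of the basis unit.
    """
    if not (0 < yield_mol_fraction <= 1):
        raise ValueError("yield must be in (0, 1]")
    b, r = basis_unit.as_dict(), retained.as_dict()
    if any(r.get(k, 0) > b.get(k, 0) for k in r):
        raise ValueError("retained formula exceeds the basis unit element-wise")
    stoich = molecular_weight(retained) / molecular_weight(basis_unit)
    return EfficiencyResult(
        stoichiometric_fraction=stoich,
        actual_fraction=stoich * yield_mol_fraction,
        basis=basis,
    )


# ---------------------------------------------------------------------------
# solvent-space metrics
# ---------------------------------------------------------------------------


def hsp_distance(a: tuple[float, float, float], b: tuple[float, float, float]) -> float:
    """Hansen distance Ra = sqrt(4ΔδD² + ΔδP² + ΔδH²), MPa^0.5.

    Symmetric and zero iff identical; the conventional factor 4 on the
    dispersion term means Ra is *not* a metric (no triangle inequality).
    """
    dd, dp, dh = (a[i] - b[i] for i in range(3))
    return math.sqrt(4 * dd * dd + dp * dp + dh * dh)


def kat_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Euclidean distance in the Kamlet–Taft (π*, β) plane."""
    return math.hypot(a[0] - b[0], a[1] - b[1])


@dataclass
class SolventRecord:
    """One solvent with its physical and solvation descriptors."""

    name: str
    formula: Formula | None = None
    mw: float | None = None  # g/mol
    density: float | None = None  # g/mL
    density_temp_C: float | None = None
    kat: tuple[float, float, float] | None = None  # (α, β, π*)
    hsp: tuple[float, float, float] | None = None  # (δD, δP, δH), MPa^0.5
    nile_red_lambda_max: float | None = None  # nm

    def __post_init__(self) -> None:
        if self.formula is not None and self.mw is not None:
            calc = molecular_weight(self.formula)
            if abs(calc - self.mw) > 0.011:
                raise ValueError(
                    f"{self.name}: tabulated MW {self.mw} inconsistent with "
                    f"formula {self.formula.hill()} ({calc:.2f})"
                )

    @property
    def molar_volume(self) -> float | None:
        """Vm = MW / density, mL/mol (at the tabulated density temperature)."""
        if self.mw is None or self.density is None:
            return None
        return self.mw / self.density


def load_solvent_table(path: str | Path | None = None) -> dict[str, SolventRecord]:
    """Load the bundled (or a user) TSV of solvent properties."""
    import pandas as pd

    if path is None:
        src = resources.files("cavistat").joinpath("data/solvent_table.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out: dict[str, SolventRecord] = {}
    for _, row in df.iterrows():
        def num(col):
            v = row.get(col)
            return None if pd.isna(v) else float(v)

        rec = SolventRecord(
            name=str(row["name"]),
            formula=parse_formula(str(row["formula"])) if not pd.isna(row["formula"]) else None,
            mw=num("mw"),
            density=num("density"),
            density_temp_C=num("density_temp_C"),
            kat=(num("alpha") or 0.0, num("beta"), num("pi_star"))
            if not pd.isna(row.get("beta"))
            else None,
            hsp=(num("dD"), num("dP"), num("dH")) if not pd.isna(row.get("dD")) else None,
            nile_red_lambda_max=num("nile_red_lambda_max"),
        )
        out[rec.name] = rec
    return out


def kat_nearest(
    query: tuple[float, float],
    reference: dict[str, SolventRecord] | dict[str, tuple[float, float]],
) -> list[tuple[str, float]]:
    """Solvents ranked by distance to ``query = (π*, β)``; ties by name.

    ``reference`` maps names either to SolventRecords (their KAT values
    are used) or directly to (π*, β) tuples.
    """
    if not reference:
        raise ValueError("reference table is empty")
    ranked = []
    for name, val in reference.items():
        if isinstance(val, SolventRecord):
            if val.kat is None:
                continue
            point = (val.kat[2], val.kat[1])  # (π*, β)
        else:
            point = (float(val[0]), float(val[1]))
        ranked.append((name, kat_distance(query, point)))
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked
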