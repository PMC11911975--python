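"""Molecular structures, trajectories and selections.

File reading (PDB, GRO, multi-model PDB, XYZ) is delegated to MDAnalysis;
this module wraps the result in a light, array-backed :class:`Trajectory`
so that downstream grid and descriptor code is format-agnostic. All
internal coordinates are in Å (GRO nm values are converted on read) and
atom indices are 0-based; residue ids are kept as authored (1-based in
PDB) because active sites are conventionally named that way (Ser105,
His224, Asp187 in CaLB).

Trajectories are assumed whole-molecule / already imaged: no periodic
boundary treatment is applied anywhere downstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .elements import ATOMIC_WEIGHTS, atomic_weight, vdw_radius

ROLE_PROTEIN = "protein"
ROLE_SOLVENT = "solvent"
ROLE_OTHER = "other"

#: standard amino-acid residue names used for automatic role assignment
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}

#: common water / solvent residue names
SOLVENT_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "SLV"}


class ParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


@dataclass
class Atom:
    """One atom of a topology.

    ``serial`` is the 0-based internal index; ``residue_id`` keeps the
    author numbering of the input file.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str = ""
    mass: float = 0.0
    vdw_radius: float = 0.0
    role: str = ROLE_OTHER

    @property
    def is_heavy(self) -> bool:
        """Heavy atom ⇔ element is not hydrogen."""
        return self.element.capitalize() != "H"


@dataclass
class Frame:
    """Coordinates of one trajectory frame, Å."""

    coordinates: np.ndarray  # (N, 3) float64
    box: np.ndarray | None = None  # 3 box lengths, Å, or None
    time_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("frame coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("frame contains non-finite coordinates")


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    atoms: list[Atom]
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = len(self.atoms)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {fr.coordinates.shape[0]} coordinates "
                    f"for a topology of {n} atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self, frame_index: int = 0) -> np.ndarray:
        return self.frames[frame_index].coordinates

    # -- vectorised per-atom attributes ------------------------------------
    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def roles(self) -> np.ndarray:
        return np.array([a.role for a in self.atoms])

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms])


@dataclass
class ActiveSiteSpec:
    """Residues that define the active site (author numbering).

    ``atom_subset`` restricts seed-zone atoms to heavy atoms ("heavy",
    the default) or keeps hydrogens ("all").
    """

    residue_ids: list[int]
    atom_subset: str = "heavy"

    def __post_init__(self) -> None:
        if not self.residue_ids:
            raise ValueError("active site must name at least one residue")
        if self.atom_subset not in ("heavy", "all"):
            raise ValueError("atom_subset must be 'heavy' or 'all'")

    def atom_indices(self, trajectory: Trajectory) -> np.ndarray:
        """Sorted indices of the active-site atoms in the topology."""
        wanted = set(self.residue_ids)
        present = set(int(r) for r in trajectory.residue_ids)
        missing = wanted - present
        if missing:
            raise ValueError(f"active-site residues {sorted(missing)} absent from topology")
        idx = [
            a.serial
            for a in trajectory.atoms
            if a.residue_id in wanted and (self.atom_subset == "all" or a.is_heavy)
        ]
        return np.array(sorted(idx), dtype=int)


# ---------------------------------------------------------------------------
# element / role inference
# ---------------------------------------------------------------------------

_NAME_PREFIX = re.compile(r"[A-Za-z]+")


def infer_element(atom_name: str, element_field: str = "") -> str:
    """Resolve an element symbol from a PDB element column or atom name.

    Prefers the element column; otherwise uses the leading letters of the
    atom name, trying a single-letter organic element first (so CA in a
    protein context is carbon, not calcium) and then a two-letter symbol.
    """
    el = element_field.strip().capitalize()
    if el and el in ATOMIC_WEIGHTS:
        return el
    m = _NAME_PREFIX.search(atom_name.strip())
    if not m:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    letters = m.group(0)
    one = letters[0].upper()
    if one in ATOMIC_WEIGHTS:
        return one
    two = letters[:2].capitalize()
    if two in ATOMIC_WEIGHTS:
        return two
    raise ParseError(f"unknown element for atom name {atom_name!r}")


def infer_role(residue_name: str, solvent_resnames: Iterable[str] | None = None) -> str:
    rn = residue_name.strip().upper()
    extra = {s.upper() for s in solvent_resnames} if solvent_resnames else set()
    if rn in SOLVENT_RESNAMES or rn in extra:
        return ROLE_SOLVENT
    if rn in PROTEIN_RESNAMES:
        return ROLE_PROTEIN
    return ROLE_OTHER


# ---------------------------------------------------------------------------
# readers (MDAnalysis-backed)
# ---------------------------------------------------------------------------

_MDA_FORMATS = {"pdb": "PDB", "gro": "GRO", "multimodel_pdb": "PDB", "xyz": "XYZ"}


def _universe(path: str | Path, fmt: str | None):
    import MDAnalysis as mda

    kwargs = {}
    if fmt is not None:
        key = fmt.lower()
        if key not in _MDA_FORMATS:
            raise ValueError(f"unsupported format {fmt!r}; expected one of {sorted(_MDA_FORMATS)}")
        kwargs["format"] = _MDA_FORMATS[key]
        kwargs["topology_format"] = _MDA_FORMATS[key]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path), **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ParseError(f"cannot parse {path.name}: {exc}") from exc


def _atoms_from_universe(u, solvent_resnames: Iterable[str] | None) -> list[Atom]:
    names = u.atoms.names if hasattr(u.atoms, "names") else [""] * len(u.atoms)
    try:
        elements = list(u.atoms.elements)
    except Exception:  # noqa: BLE001 - element column absent, infer from names
        elements = [""] * len(u.atoms)
    resnames = (
        u.atoms.resnames if hasattr(u.atoms, "resnames") else ["UNK"] * len(u.atoms)
    )
    resids = u.atoms.resids if hasattr(u.atoms, "resids") else np.ones(len(u.atoms), int)
    try:
        chains = list(u.atoms.chainIDs)
    except Exception:  # noqa: BLE001
        chains = [""] * len(u.atoms)

    atoms: list[Atom] = []
    for i in range(len(u.atoms)):
        name = str(names[i])
        element = infer_element(name if name else str(elements[i]), str(elements[i]))
        resname = str(resnames[i])
        atoms.append(
            Atom(
                serial=i,
                name=name or element,
                element=element,
                residue_name=resname,
                residue_id=int(resids[i]),
                chain=str(chains[i]).strip(),
                mass=atomic_weight(element),
                role=infer_role(resname, solvent_resnames),
            )
        )
    return atoms


def read_structure(
    path: str | Path,
    format: str | None = None,
    solvent_resnames: Iterable[str] | None = None,
) -> Trajectory:
    """Read a single-frame structure (PDB or GRO) into a :class:`Trajectory`.

    Coordinates are returned in Å; masses are filled from the bundled
    atomic-weight table and roles assigned from residue names. vdW radii
    are left at 0 until :func:`assign_radii` is called.
    """
    u = _universe(path, format)
    atoms = _atoms_from_universe(u, solvent_resnames)
    coords = np.array(u.atoms.positions, dtype=float)  # MDAnalysis is Å-native
    box = None
    if u.dimensions is not None and np.all(np.asarray(u.dimensions)[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=float)
    return Trajectory(atoms=atoms, frames=[Frame(coords, box=box, time_index=0)])


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    solvent_resnames: Iterable[str] | None = None,
) -> Trajectory:
    """Read a multi-frame trajectory (multi-model PDB or XYZ).

    Frames keep file order; every frame must have the same atom count
    (enforced by the reader, reported with the offending frame index).
    """
    u = _universe(path, format)
    atoms = _atoms_from_universe(u, solvent_resnames)
    frames: list[Frame] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, ts in enumerate(u.trajectory):
                if ts.positions.shape[0] != len(atoms):
                    raise ParseError(
                        f"frame {k} has {ts.positions.shape[0]} atoms, expected {len(atoms)}"
                    )
                box = None
                if ts.dimensions is not None and np.all(np.asarray(ts.dimensions)[:3] > 0):
                    box = np.asarray(ts.dimensions[:3], dtype=float)
                frames.append(Frame(np.array(ts.positions, dtype=float), box=box, time_index=k))
    except ParseError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot read frames of {Path(path).name}: {exc}") from exc
    return Trajectory(atoms=atoms, frames=frames)


# ---------------------------------------------------------------------------
# writer (multi-model PDB)
# ---------------------------------------------------------------------------


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (fixed-column, %8.3f).

    Round-tripping through :func:`read_trajectory` reproduces coordinates
    to the format precision (±0.001 Å).
    """
    path = Path(path)
    lines: list[str] = []
    multi = trajectory.n_frames > 1
    for k, fr in enumerate(trajectory.frames):
        if multi:
            lines.append(f"MODEL     {k + 1:4d}")
        for a, xyz in zip(trajectory.atoms, fr.coordinates):
            serial = (a.serial + 1) % 100000
            resid = a.residue_id % 10000
            name = a.name[:4]
            # PDB convention: 1–3 char names start in column 14
            name_f = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {name_f}{'':1s}{a.residue_name[:3]:>3s} "
                f"{(a.chain or 'A')[:1]}{resid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element.rjust(2)[:2]}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_xyz(trajectory: Trajectory, path: str | Path) -> None:
    """Write frames as concatenated XYZ blocks (element x y z, Å)."""
    path = Path(path)
    out: list[str] = []
    for k, fr in enumerate(trajectory.frames):
        out.append(str(trajectory.n_atoms))
        out.append(f"frame {k}")
        for a, xyz in zip(trajectory.atoms, fr.coordinates):
            out.append(f"{a.element} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# radii and selections
# ---------------------------------------------------------------------------


def assign_radii(
    trajectory: Trajectory,
    radius_set: str = "default",
    default_radius: float | None = None,
    overrides: dict[str, float] | None = None,
) -> Trajectory:
    """Assign vdW radii in place from a named bundled table.

    ``overrides`` maps element symbols to radii and wins over the table;
    ``default_radius`` covers elements absent from both. An element not
    covered by any source raises, naming the atom.
    """
    overrides = {k.capitalize(): float(v) for k, v in (overrides or {}).items()}
    for a in trajectory.atoms:
        sym = a.element.capitalize()
        if sym in overrides:
            a.vdw_radius = overrides[sym]
            continue
        try:
            a.vdw_radius = vdw_radius(sym, radius_set, default=default_radius)
        except KeyError as exc:
            raise KeyError(f"atom {a.serial} ({a.name}): {exc.args[0]}") from None
    return trajectory


def select(
    trajectory: Trajectory,
    role: str | None = None,
    heavy: bool | None = None,
    residue_ids: Sequence[int] | None = None,
    residue_names: Sequence[str] | None = None,
    elements: Sequence[str] | None = None,
) -> np.ndarray:
    """Deterministic, sorted atom-index selection by conjunction of criteria.

    An empty result emits a warning and returns an empty array rather
    than raising — downstream code treats empty selections explicitly.
    """
    rid_set = set(int(r) for r in residue_ids) if residue_ids is not None else None
    rn_set = {r.upper() for r in residue_names} if residue_names is not None else None
    el_set = {e.capitalize() for e in elements} if elements is not None else None
    out = []
    for a in trajectory.atoms:
        if role is not None and a.role != role:
            continue
        if heavy is not None and a.is_heavy != heavy:
            continue
        if rid_set is not None and a.residue_id not in rid_set:
            continue
        if rn_set is not None and a.residue_name.upper() not in rn_set:
            continue
        if el_set is not None and a.element.capitalize() not in el_set:
            continue
        out.append(a.serial)
    if not out:
        warnings.warn("selection matched no atoms", stacklevel=2)
    return np.array(sorted(out), dtype=int)
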