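"""Synthetic structures with known ground truth for pipeline validation.

Real enzyme trajectories have no analytically known cavity volume, so
every stage of the cavity/descriptor pipeline is exercised on generated
fixtures instead:

* :func:`make_shell` builds a closed cubic shell of lattice "wall"
  atoms around an interior pocket of controlled size, with three
  designated triad atoms on the inner wall playing the catalytic-triad
  role, and, optionally, a gate of atoms across a mid-plane that can be
  closed (splitting the pocket in two, the way a flexing enzyme can
  split its active-site cavity) or open (parked inside the wall).
* :func:`place_solvent` drops rigid random heavy-atom clusters into the
  pocket or outside the shell at a controlled count, emulating solvent
  molecules of 5 (small-acetal-like) to 18 (large-acetal-like) heavy
  atoms.
* :func:`jitter` adds i.i.d. Gaussian positional noise per frame as a
  stand-in for thermal fluctuation.
* :func:`make_two_state` interleaves two conformations into one
  trajectory for clustering and gate-tracking tests.

Ground truth (interior free volume, component count) is computed by a
brute-force fine-grid oracle over the pocket region, not by the cavity
engine under test, and ships with the fixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .elements import vdw_radius
from .structure import Atom, Frame, ROLE_PROTEIN, ROLE_SOLVENT, Trajectory, write_pdb

#: residue ids given to the three designated triad atoms (Ser/His/Asp
#: author numbering of the CaLB triad, so ActiveSiteSpec([105, 224, 187])
#: works on fixtures and real structures alike)
TRIAD_RESIDUE_IDS = (105, 224, 187)
_TRIAD_RESNAMES = ("SER", "HIS", "ASP")


@dataclass
class ShellSpec:
    """Geometry of a closed shell with an interior pocket.

    ``inner_box`` is the pocket's lattice-to-lattice extent (a, b, c) in
    Å; the analytic free region is smaller by the wall element's vdW
    radius on each side. ``gate_plane`` (x position, Å) adds gate atoms
    across the pocket that split it when closed.
    """

    inner_box: tuple[float, float, float] = (10.0, 10.0, 10.0)
    wall_thickness: float = 4.0
    lattice_spacing: float = 1.0
    atom_element: str = "C"
    gate_plane: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        r = vdw_radius(self.atom_element)
        if self.wall_thickness < 2 * r:
            raise ValueError(
                f"wall_thickness {self.wall_thickness} < 2×vdW radius {2 * r}: shell would leak"
            )
        if min(self.inner_box) < 2.0:
            raise ValueError("inner box must be at least 2 Å per axis")


@dataclass
class ShellGroundTruth:
    """Machine-readable ground truth shipped with a shell fixture."""

    free_volume_A3: float
    component_volumes_A3: list[float]
    n_components: int
    triad_indices: list[int]
    oracle_spacing_A: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True) + "\n")

    @staticmethod
    def from_json(path: str | Path) -> "ShellGroundTruth":
        return ShellGroundTruth(**json.loads(Path(path).read_text()))


@dataclass
class SolventSpec:
    """Placement request for rigid solvent-like heavy-atom clusters."""

    n_molecules: int
    heavy_atoms_per_molecule: int = 5
    cluster_radius: float = 2.0  # Å; ~2 for a 5-atom, ~3.5 for an 18-atom molecule
    placement_region: str = "cavity"  # cavity | shell_exterior | both
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 0 or self.heavy_atoms_per_molecule < 1:
            raise ValueError("need n_molecules ≥ 0 and ≥1 heavy atom per molecule")
        if self.placement_region not in ("cavity", "shell_exterior", "both"):
            raise ValueError("placement_region must be cavity, shell_exterior or both")


# ---------------------------------------------------------------------------


def _shell_lattice(spec: ShellSpec, gate_open: bool) -> tuple[np.ndarray, list[int]]:
    """Wall + gate atom positions; returns (positions, gate indices)."""
    a, b, c = spec.inner_box
    s = spec.lattice_spacing
    n_wall = int(np.ceil(spec.wall_thickness / s))
    ax = np.arange(-n_wall, int(round(a / s)) + n_wall + 1) * s
    ay = np.arange(-n_wall, int(round(b / s)) + n_wall + 1) * s
    az = np.arange(-n_wall, int(round(c / s)) + n_wall + 1) * s
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    interior = (
        (pts[:, 0] > 0) & (pts[:, 0] < a)
        & (pts[:, 1] > 0) & (pts[:, 1] < b)
        & (pts[:, 2] > 0) & (pts[:, 2] < c)
    )
    wall = pts[~interior]
    gate_idx: list[int] = []
    if spec.gate_plane is not None:
        gpos = []
        for y in ay[(ay > 0) & (ay < b)]:
            for z in az[(az > 0) & (az < c)]:
                gpos.append((spec.gate_plane, y, z))
        gpos = np.array(gpos)
        if gate_open:
            # park gate atoms inside the wall slab below the pocket
            gpos = gpos.copy()
            gpos[:, 2] = -spec.wall_thickness / 2 + 0.5
        gate_idx = list(range(len(wall), len(wall) + len(gpos)))
        wall = np.vstack([wall, gpos])
    return wall, gate_idx


def _pick_triad(positions: np.ndarray, spec: ShellSpec) -> list[int]:
    """Three distinct inner-wall sites near the center of the x=0 face."""
    b, c = spec.inner_box[1], spec.inner_box[2]
    on_face = np.flatnonzero(
        (positions[:, 0] == 0)
        & (positions[:, 1] > 0) & (positions[:, 1] < b)
        & (positions[:, 2] > 0) & (positions[:, 2] < c)
    )
    center = np.array([0.0, b / 2, c / 2])
    order = np.argsort(np.linalg.norm(positions[on_face] - center, axis=1), kind="stable")
    if len(order) < 3:
        raise ValueError("inner face too small to host three triad atoms")
    return [int(on_face[i]) for i in order[:3]]


def _fine_grid_oracle(
    positions: np.ndarray, radius: float, spec: ShellSpec, oracle_spacing: float
) -> tuple[float, list[float], int]:
    """Brute-force free-volume oracle over the pocket region.

    Counts fine-grid cells inside a margin around the inner box whose
    centers clear every wall atom's vdW sphere, labels their connected
    components, and verifies the pocket does not leak to the region
    boundary (walls thicker than the margin guarantee boundary cells are
    occupied if and only if the shell is tight).
    """
    a, b, c = spec.inner_box
    margin = 1.0
    axes = [
        np.arange(-margin + oracle_spacing / 2, ext + margin, oracle_spacing)
        for ext in (a, b, c)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(positions)
    d, _ = tree.query(centers, k=1, distance_upper_bound=radius + 1e-12)
    free = ~np.isfinite(d) | (d > radius)
    free = free.reshape(gx.shape)
    # leak check: no free cell may touch the region boundary
    if (
        free[0].any() or free[-1].any()
        or free[:, 0].any() or free[:, -1].any()
        or free[:, :, 0].any() or free[:, :, -1].any()
    ):
        raise ValueError("shell leaks: oracle flood fill reaches the region boundary")
    labels, n = ndimage.label(free, structure=ndimage.generate_binary_structure(3, 3))
    cell = oracle_spacing**3
    comp_vols = sorted(
        (float(np.sum(labels == k) * cell) for k in range(1, n + 1)), reverse=True
    )
    return float(free.sum() * cell), comp_vols, n


def make_shell(
    spec: ShellSpec,
    gate_open: bool = True,
    oracle_spacing: float = 0.1,
) -> tuple[Trajectory, ShellGroundTruth]:
    """Closed cubic shell with interior pocket, triad atoms and ground truth.

    All atoms are role=protein; the three triad atoms get residue ids
    105/224/187 so the standard active-site spec selects them. The
    ground-truth free volume and component count come from an
    independent fine-grid oracle run at generation time.
    """
    positions, gate_idx = _shell_lattice(spec, gate_open)
    triad = _pick_triad(positions, spec)
    r = vdw_radius(spec.atom_element)
    volume, comp_vols, n_comp = _fine_grid_oracle(positions, r, spec, oracle_spacing)

    atoms = []
    triad_map = {t: k for k, t in enumerate(triad)}
    for i in range(len(positions)):
        if i in triad_map:
            k = triad_map[i]
            resname, resid = _TRIAD_RESNAMES[k], TRIAD_RESIDUE_IDS[k]
        elif i in gate_idx:
            resname, resid = "GAT", 2
        else:
            resname, resid = "WAL", 1
        atoms.append(
            Atom(
                serial=i,
                name=spec.atom_element,
                element=spec.atom_element,
                residue_name=resname,
                residue_id=resid,
                chain="A",
                mass=12.011,
                vdw_radius=r,
                role=ROLE_PROTEIN,
            )
        )
    traj = Trajectory(atoms=atoms, frames=[Frame(positions.astype(float), time_index=0)])
    gt = ShellGroundTruth(
        free_volume_A3=volume,
        component_volumes_A3=comp_vols,
        n_components=n_comp,
        triad_indices=triad,
        oracle_spacing_A=oracle_spacing,
    )
    return traj, gt


# ---------------------------------------------------------------------------


def place_solvent(
    structure: Trajectory,
    spec: SolventSpec,
    inner_box: tuple[float, float, float] = (10.0, 10.0, 10.0),
    element: str = "O",
    clearance: float = 2.1,
    max_attempts: int = 100_000,
) -> Trajectory:
    """Add rigid random solvent clusters to a shell structure.

    Molecules are placed by rejection sampling: a candidate is accepted
    when every atom keeps ``clearance`` Å from all wall atoms and from
    previously placed solvent atoms, and (for the cavity region) stays
    inside the pocket's free box. Deterministic under ``spec.seed``;
    raises if the request cannot be placed within ``max_attempts``.
    """
    rng = np.random.default_rng(spec.seed)
    wall = structure.coordinates(0)
    tree = cKDTree(wall)
    a, b, c = inner_box
    lo_cav = np.array([clearance, clearance, clearance])
    hi_cav = np.array([a, b, c]) - clearance
    if np.any(hi_cav <= lo_cav):
        raise ValueError("pocket too small for the requested clearance")
    ext_lo = wall.min(axis=0) - 6.0
    ext_hi = wall.max(axis=0) + 6.0

    placed: list[np.ndarray] = []
    attempts = 0
    for mol in range(spec.n_molecules):
        if spec.placement_region == "both":
            region = "cavity" if mol % 2 == 0 else "shell_exterior"
        else:
            region = spec.placement_region
        # rigid template: first atom at the center, the rest in a ball
        offsets = np.zeros((spec.heavy_atoms_per_molecule, 3))
        if spec.heavy_atoms_per_molecule > 1:
            raw = rng.normal(size=(spec.heavy_atoms_per_molecule - 1, 3))
            raw /= np.linalg.norm(raw, axis=1)[:, None]
            offsets[1:] = raw * rng.uniform(0, spec.cluster_radius, size=(len(raw), 1))
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place molecule {mol} without overlap in {max_attempts} attempts"
                )
            if region == "cavity":
                center = rng.uniform(lo_cav, hi_cav)
            else:
                center = rng.uniform(ext_lo, ext_hi)
                # reject candidates inside the shell's bounding box
                if np.all(center > wall.min(axis=0) - 2.0) and np.all(
                    center < wall.max(axis=0) + 2.0
                ):
                    continue
            cand = center + offsets
            if region == "cavity" and (
                np.any(cand < lo_cav - 0.2) or np.any(cand > hi_cav + 0.2)
            ):
                continue
            d, _ = tree.query(cand, k=1)
            if np.min(d) < clearance:
                continue
            if placed and cKDTree(np.vstack(placed)).query(cand, k=1)[0].min() < 1.0:
                continue
            placed.append(cand)
            break

    n0 = structure.n_atoms
    atoms = list(structure.atoms)
    coords = [wall]
    for m, mol_coords in enumerate(placed):
        for j in range(len(mol_coords)):
            atoms.append(
                Atom(
                    serial=n0 + m * spec.heavy_atoms_per_molecule + j,
                    name=element,
                    element=element,
                    residue_name="SLV",
                    residue_id=1000 + m,
                    chain="S",
                    mass=15.999,
                    vdw_radius=vdw_radius(element),
                    role=ROLE_SOLVENT,
                )
            )
        coords.append(mol_coords)
    all_coords = np.vstack(coords)
    return Trajectory(atoms=atoms, frames=[Frame(all_coords, time_index=0)])


def jitter(trajectory: Trajectory, sigma: float, n_frames: int, seed: int = 0) -> Trajectory:
    """Expand a structure into frames of i.i.d. Gaussian positional noise.

    Frame k = base + N(0, σ²) per coordinate; σ = 0 replicates the base
    frame. Deterministic under ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    base = trajectory.coordinates(0)
    frames = [
        Frame(base + rng.normal(0.0, sigma, size=base.shape) if sigma > 0 else base.copy(),
              time_index=k)
        for k in range(n_frames)
    ]
    return Trajectory(atoms=list(trajectory.atoms), frames=frames)


def make_two_state(
    trajectory_a: Trajectory, trajectory_b: Trajectory, pattern: str = "ABAB"
) -> Trajectory:
    """Interleave the first frames of two conformations per a pattern string."""
    if trajectory_a.n_atoms != trajectory_b.n_atoms:
        raise ValueError("topology mismatch: different atom counts")
    for x, y in zip(trajectory_a.atoms, trajectory_b.atoms):
        if x.name != y.name or x.element != y.element:
            raise ValueError(f"topology mismatch at atom {x.serial}")
    if not pattern or set(pattern.upper()) - {"A", "B"}:
        raise ValueError("pattern must be a non-empty string over {A, B}")
    frames = []
    for k, ch in enumerate(pattern.upper()):
        src = trajectory_a if ch == "A" else trajectory_b
        frames.append(Frame(src.coordinates(0).copy(), time_index=k))
    return Trajectory(atoms=list(trajectory_a.atoms), frames=frames)


# ---------------------------------------------------------------------------
# named presets (used by the CLI and the examples)
# ---------------------------------------------------------------------------


def make_preset(name: str, seed: int = 0, outdir: str | Path | None = None):
    """Build a named fixture preset; optionally write PDB + ground-truth JSON.

    Presets: ``box_pocket`` (plain shell), ``gated_pocket`` (closed gate,
    two sub-pockets), ``two_state`` (gate alternating open/closed over 4
    frames), ``crowded_cavity`` (pocket holding 38 solvent heavy atoms
    in ~1 nm³, the density regime of a large acetal solvent).
    """
    if name == "box_pocket":
        traj, gt = make_shell(ShellSpec(seed=seed))
    elif name == "gated_pocket":
        traj, gt = make_shell(ShellSpec(inner_box=(12.0, 6.0, 6.0), gate_plane=6.0, seed=seed),
                              gate_open=False)
    elif name == "two_state":
        spec = ShellSpec(inner_box=(12.0, 6.0, 6.0), gate_plane=6.0, seed=seed)
        open_traj, gt = make_shell(spec, gate_open=True)
        closed_traj, _ = make_shell(spec, gate_open=False)
        traj = make_two_state(open_traj, closed_traj, "ABAB")
    elif name == "crowded_cavity":
        # ~0.9 nm³ pocket filled to the ~38 heavy atoms / nm³ regime of a
        # bulky acetal solvent
        inner = (13.0, 13.0, 13.0)
        shell, gt = make_shell(ShellSpec(inner_box=inner, seed=seed))
        n = round(38 * gt.free_volume_A3 / 1000.0)
        traj = place_solvent(
            shell,
            SolventSpec(n_molecules=n, heavy_atoms_per_molecule=1, seed=seed),
            inner_box=inner,
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; available: box_pocket, gated_pocket, two_state, crowded_cavity"
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pdb(traj, outdir / f"{name}.pdb")
        gt.to_json(outdir / f"{name}.ground_truth.json")
    return traj, gt
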