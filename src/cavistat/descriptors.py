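"""Rigidity and interaction descriptors for enzyme trajectories.

Covers the descriptors conventionally used to judge how a solvent
affects enzyme structure and dynamics:

* radius of gyration (compactness),
* geometric hydrogen bonds (H···A distance + D–H···A angle criterion),
* named atom-pair distance series (e.g. the catalytic-triad contacts
  Ser105:OG–His224:NE2 and Asp187:OD2–His224:ND1 of a serine hydrolase),
* least-squares superposition RMSD (Kabsch), and
* neighbour-count (medoid-removal) conformational clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import Trajectory

#: maximum covalent D–H bond length used to find a donor's hydrogens, Å
COVALENT_DH_MAX = 1.25


@dataclass
class HBond:
    """One detected hydrogen bond in one frame."""

    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    distance_HA: float  # Å
    angle_DHA: float  # degrees


@dataclass
class ClusterResult:
    """Conformational clusters from the neighbour-count algorithm."""

    cutoff: float  # Å
    assignments: np.ndarray  # frame -> cluster id (0-based, ordered by size)
    medoids: list[int]
    sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)


# ---------------------------------------------------------------------------


def radius_of_gyration(
    frame_coords: np.ndarray,
    indices: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """Rg = sqrt( Σ mᵢ‖rᵢ − r_com‖² / Σ mᵢ ), Å.

    Unweighted (``mass_weighted=False``) uses unit masses. Invariant
    under global rotation and translation.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("radius of gyration of an empty selection is undefined")
    pts = np.asarray(frame_coords, dtype=float)[idx]
    if mass_weighted:
        if masses is None:
            raise ValueError("mass-weighted Rg requires masses")
        m = np.asarray(masses, dtype=float)[idx]
        if np.any(m <= 0):
            raise ValueError("all selected atoms need positive masses")
    else:
        m = np.ones(len(idx))
    com = (pts * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((pts - com) ** 2).sum(axis=1)).sum() / m.sum()))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _donor_hydrogens(
    trajectory: Trajectory, frame_coords: np.ndarray, donor: int
) -> list[int]:
    """Hydrogens covalently attached to a donor.

    Resolution convention: hydrogen atoms of the same residue whose name
    starts with H and that sit within COVALENT_DH_MAX of the donor in
    this frame.
    """
    da = trajectory.atoms[donor]
    coords = np.asarray(frame_coords, dtype=float)
    out = []
    for a in trajectory.atoms:
        if a.is_heavy or a.residue_id != da.residue_id or a.chain != da.chain:
            continue
        if np.linalg.norm(coords[a.serial] - coords[donor]) <= COVALENT_DH_MAX:
            out.append(a.serial)
    return out


def detect_hbonds(
    trajectory: Trajectory,
    frame_index: int,
    donors: Sequence[int],
    acceptors: Sequence[int],
    dist_cutoff: float = 2.5,
    angle_cutoff: float = 135.0,
) -> list[HBond]:
    """Geometric hydrogen bonds in one frame.

    A bond D–H···A is reported iff H···A ≤ ``dist_cutoff`` (Å) and the
    D–H···A angle ≥ ``angle_cutoff`` (degrees), with D ≠ A. Donors
    without a resolvable hydrogen are skipped with a warning. The result
    is sorted (donor, acceptor) and independent of input order.
    """
    coords = trajectory.coordinates(frame_index)
    acc = sorted(set(int(a) for a in acceptors))
    if not acc:
        return []
    acc_tree = cKDTree(coords[acc])
    bonds: list[HBond] = []
    for d in sorted(set(int(x) for x in donors)):
        hydrogens = _donor_hydrogens(trajectory, coords, d)
        if not hydrogens:
            warnings.warn(
                f"donor atom {d} ({trajectory.atoms[d].name}) has no resolvable hydrogen; skipped",
                stacklevel=2,
            )
            continue
        for h in hydrogens:
            for j in acc_tree.query_ball_point(coords[h], dist_cutoff):
                a = acc[j]
                if a == d or a == h:
                    continue
                v_hd = coords[d] - coords[h]
                v_ha = coords[a] - coords[h]
                dist = float(np.linalg.norm(v_ha))
                denom = np.linalg.norm(v_hd) * dist
                if denom == 0:
                    continue
                cosang = np.clip(np.dot(v_hd, v_ha) / denom, -1.0, 1.0)
                angle = float(np.degrees(np.arccos(cosang)))
                if dist <= dist_cutoff and angle >= angle_cutoff:
                    bonds.append(HBond(d, h, a, dist, angle))
    bonds.sort(key=lambda b: (b.donor_atom, b.acceptor_atom, b.hydrogen_atom))
    return bonds


def hbond_count_timeseries(
    trajectory: Trajectory,
    donors: Sequence[int],
    acceptors: Sequence[int],
    dist_cutoff: float = 2.5,
    angle_cutoff: float = 135.0,
) -> np.ndarray:
    """Number of detected hydrogen bonds in each frame."""
    return np.array(
        [
            len(detect_hbonds(trajectory, k, donors, acceptors, dist_cutoff, angle_cutoff))
            for k in range(trajectory.n_frames)
        ],
        dtype=int,
    )


def hbond_occupancy(
    trajectory: Trajectory,
    donor: int,
    acceptor: int,
    dist_cutoff: float = 2.5,
    angle_cutoff: float = 135.0,
) -> float:
    """Fraction of frames in which a specific D→A bond is present ∈ [0, 1]."""
    present = 0
    for k in range(trajectory.n_frames):
        bonds = detect_hbonds(trajectory, k, [donor], [acceptor], dist_cutoff, angle_cutoff)
        present += any(b.donor_atom == donor and b.acceptor_atom == acceptor for b in bonds)
    return present / trajectory.n_frames


# ---------------------------------------------------------------------------
# named-pair distances
# ---------------------------------------------------------------------------


def _atom_by_residue_and_name(trajectory: Trajectory, residue_id: int, name: str) -> int:
    for a in trajectory.atoms:
        if a.residue_id == residue_id and a.name == name:
            return a.serial
    raise ValueError(f"no atom {name!r} in residue {residue_id}")


def triad_distances(
    trajectory: Trajectory,
    pairs: Sequence[tuple[tuple[int, str], tuple[int, str]]],
) -> "pd.DataFrame":
    """Per-frame Euclidean distances for named atom pairs.

    Each pair is ((residue_id, atom_name), (residue_id, atom_name)),
    e.g. ``((105, "OG"), (224, "NE2"))`` for the Ser–His contact of a
    catalytic triad. Columns are labelled ``resid:name-resid:name``.
    """
    import pandas as pd

    cols = {}
    for (ra, na), (rb, nb) in pairs:
        ia = _atom_by_residue_and_name(trajectory, ra, na)
        ib = _atom_by_residue_and_name(trajectory, rb, nb)
        dist = [
            float(np.linalg.norm(fr.coordinates[ia] - fr.coordinates[ib]))
            for fr in trajectory.frames
        ]
        cols[f"{ra}:{na}-{rb}:{nb}"] = dist
    df = pd.DataFrame(cols)
    df.insert(0, "frame", np.arange(trajectory.n_frames))
    return df


# ---------------------------------------------------------------------------
# superposition and clustering
# ---------------------------------------------------------------------------


def superpose_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares superposition of b onto a (Kabsch, proper rotation).

    Returns ``(rmsd, rotation, translation)`` such that
    ``coords_b @ rotation.T + translation`` best fits ``coords_a`` over
    the fit atoms; the RMSD is measured over the fit atoms after
    fitting. Reflections are excluded by the determinant correction.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    idx = np.arange(len(a)) if fit_indices is None else np.asarray(fit_indices, dtype=int)
    if idx.size < 3:
        raise ValueError("need at least 3 fit atoms")
    pa, pb = a[idx], b[idx]
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    qa, qb = pa - ca, pb - cb
    if np.linalg.matrix_rank(qa) < 2:
        raise ValueError("fit atoms are collinear; superposition is ill-defined")
    h = qb.T @ qa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    fitted = qb @ rot.T + ca
    rmsd = float(np.sqrt(((fitted - pa) ** 2).sum() / len(idx)))
    return rmsd, rot, trans


def pairwise_rmsd_matrix(trajectory: Trajectory, fit_indices: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise fitted RMSDs over all frames."""
    n = trajectory.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r, _, _ = superpose_rmsd(
                trajectory.coordinates(i), trajectory.coordinates(j), fit_indices
            )
            mat[i, j] = mat[j, i] = r
    return mat


def cluster_conformations(
    trajectory: Trajectory,
    fit_indices: np.ndarray,
    cutoff: float = 1.0,
) -> ClusterResult:
    """Neighbour-count (medoid-removal) conformational clustering.

    Repeatedly take the unassigned frame with the most unassigned
    neighbours within ``cutoff`` (pairwise fitted RMSD) as a cluster
    medoid and remove it together with its neighbours, until no frame
    remains. Ties break on the lowest frame index; cluster ids are
    ordered by size (descending), then medoid index.
    """
    n = trajectory.n_frames
    mat = pairwise_rmsd_matrix(trajectory, fit_indices)
    neighbour = mat <= cutoff
    np.fill_diagonal(neighbour, False)
    remaining = np.ones(n, dtype=bool)
    clusters: list[tuple[int, list[int]]] = []
    while remaining.any():
        counts = (neighbour & remaining).sum(axis=1)
        counts[~remaining] = -1
        medoid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(remaining & (neighbour[medoid] | (np.arange(n) == medoid)))
        clusters.append((medoid, members.tolist()))
        remaining[members] = False
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    assignments = np.empty(n, dtype=int)
    medoids, sizes = [], []
    for cid, (medoid, members) in enumerate(clusters):
        assignments[members] = cid
        medoids.append(medoid)
        sizes.append(len(members))
    return ClusterResult(cutoff=cutoff, assignments=assignments, medoids=medoids, sizes=sizes)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def rg_timeseries(
    trajectory: Trajectory, indices: np.ndarray, mass_weighted: bool = True
) -> np.ndarray:
    masses = trajectory.masses if mass_weighted else None
    return np.array(
        [
            radius_of_gyration(fr.coordinates, indices, masses, mass_weighted)
            for fr in trajectory.frames
        ]
    )


def series_to_tsv(values: dict[str, np.ndarray], path: str | Path) -> None:
    """Write named per-frame series as a TSV with a leading frame column."""
    import pandas as pd

    df = pd.DataFrame(values)
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)
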