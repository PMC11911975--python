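"""Independent oracles, deliberately coded apart from the implementation.

* :func:`bfs_components` — breadth-first flood fill over a boolean 3-D
  mask with explicit neighbour offsets (no scipy labelling).
* :func:`quaternion_rmsd` — closed-form optimal superposition RMSD via
  the Kearsley/Horn quaternion eigenvalue method (no SVD/Kabsch).
* :func:`daura_reference` — naive re-derivation of neighbour-count
  clustering with per-iteration recomputation from scratch.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def _neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return offs


def bfs_components(free: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components of a boolean mask by BFS flood fill.

    Labels are assigned in lexicographic scan order of each component's
    first voxel, starting at 1; non-free voxels get 0.
    """
    free = np.asarray(free, dtype=bool)
    labels = np.zeros(free.shape, dtype=int)
    offs = _neighbour_offsets(connectivity)
    nx, ny, nz = free.shape
    next_label = 0
    for start in zip(*np.nonzero(free)):
        if labels[start]:
            continue
        next_label += 1
        queue = deque([start])
        labels[start] = next_label
        while queue:
            i, j, k = queue.popleft()
            for di, dj, dk in offs:
                a, b, c = i + di, j + dj, k + dk
                if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
                    if free[a, b, c] and not labels[a, b, c]:
                        labels[a, b, c] = next_label
                        queue.append((a, b, c))
    return labels


def quaternion_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Optimal superposition RMSD by the quaternion (Kearsley) method."""
    a = np.asarray(coords_a, float) - np.mean(coords_a, axis=0)
    b = np.asarray(coords_b, float) - np.mean(coords_b, axis=0)
    n = len(a)
    xm, ym, zm = (b - a).T
    xp, yp, zp = (b + a).T
    key = np.empty((4, 4))
    key[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    key[1, 1] = np.sum(xm**2 + yp**2 + zp**2)
    key[2, 2] = np.sum(xp**2 + ym**2 + zp**2)
    key[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    key[0, 1] = key[1, 0] = np.sum(yp * zm - ym * zp)
    key[0, 2] = key[2, 0] = np.sum(xm * zp - xp * zm)
    key[0, 3] = key[3, 0] = np.sum(xp * ym - xm * yp)
    key[1, 2] = key[2, 1] = np.sum(xm * ym - xp * yp)
    key[1, 3] = key[3, 1] = np.sum(xm * zm - xp * zp)
    key[2, 3] = key[3, 2] = np.sum(ym * zm - yp * zp)
    lam = np.linalg.eigvalsh(key)[0]
    return float(np.sqrt(max(lam, 0.0) / n))


def daura_reference(rmsd_matrix: np.ndarray, cutoff: float) -> tuple[list[int], list[list[int]]]:
    """Neighbour-count clustering, recomputed naively each round.

    Returns (medoids, members per cluster) in removal order.
    """
    n = len(rmsd_matrix)
    remaining = list(range(n))
    medoids, clusters = [], []
    while remaining:
        best, best_members = None, None
        for i in remaining:
            members = [j for j in remaining if j == i or rmsd_matrix[i][j] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best, best_members = i, members
        medoids.append(best)
        clusters.append(sorted(best_members))
        remaining = [j for j in remaining if j not in best_members]
    return medoids, clusters
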