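"""Independent brute-force oracles used to check the analytic code paths.

These deliberately avoid the package's own algorithms: the superposition
oracle searches rotation space on a refined grid, and the clustering
oracle is a literal transcription of the gromos procedure with explicit
Python loops.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def grid_search_rmsd(mobile: np.ndarray, target: np.ndarray,
                     final_step_deg: float = 0.1) -> float:
    """Minimum RMSD over rotations found by hierarchical grid search.

    Centroids are aligned exactly; rotations are scanned on a full Euler
    grid that is repeatedly refined around the best candidates down to
    ``final_step_deg``.  Independent of the SVD-based solution.
    """
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)

    def rmsd_for(rotvecs: np.ndarray) -> np.ndarray:
        mats = Rotation.from_euler("zyz", rotvecs, degrees=True).as_matrix()
        moved = np.einsum("rij,nj->rni", mats, a)
        diff = moved - b[None, :, :]
        return np.sqrt((diff * diff).sum(axis=(1, 2)) / a.shape[0])

    step = 15.0
    grid = np.array(np.meshgrid(
        np.arange(0.0, 360.0, step),
        np.arange(0.0, 180.0 + step, step),
        np.arange(0.0, 360.0, step),
    )).reshape(3, -1).T
    values = rmsd_for(grid)
    candidates = grid[np.argsort(values)[:10]]
    while step > final_step_deg:
        step /= 3.0
        offsets = np.array(np.meshgrid(*[np.arange(-3, 4) * step] * 3)).reshape(3, -1).T
        grid = (candidates[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        values = rmsd_for(grid)
        candidates = grid[np.argsort(values)[:10]]
    return float(values.min())


def brute_force_gromos(dmatrix: np.ndarray, cutoff: float):
    """Literal gromos clustering: nested loops, lowest-index tie-break.

    Returns (labels 1-based by decreasing population, centroids, pops).
    """
    n = dmatrix.shape[0]
    unassigned = set(range(n))
    raw = []  # (centroid, members) in discovery order
    while unassigned:
        best_item, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in sorted(unassigned) if dmatrix[i, j] <= cutoff)
            if count > best_count:
                best_item, best_count = i, count
        members = [j for j in sorted(unassigned) if dmatrix[best_item, j] <= cutoff]
        raw.append((best_item, members))
        unassigned -= set(members)
    order = sorted(range(len(raw)), key=lambda c: (-len(raw[c][1]), c))
    labels = np.zeros(n, dtype=int)
    centroids, pops = [], []
    for new_id, c in enumerate(order, start=1):
        centroid, members = raw[c]
        for m in members:
            labels[m] = new_id
        centroids.append(centroid)
        pops.append(len(members))
    return labels, centroids, pops
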