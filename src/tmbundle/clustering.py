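"""gromos conformational clustering on a mutual-RMSD matrix.

The gromos algorithm (Daura et al.): repeatedly take the unassigned item
with the most unassigned neighbors within the RMSD cutoff, make it the
centroid of a new cluster containing it and those neighbors, remove them,
and iterate until every item is assigned.  Ties on neighbor count are
broken by the lowest item index, which keeps the output deterministic and
matches the GROMACS implementation.  Cluster ids are 1-based and ordered
by decreasing population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import DistanceMatrix
from .structure_io import Structure, Trajectory

__all__ = [
    "ClusterResult",
    "gromos_cluster",
    "cluster_membership_by_source",
    "extract_centroid_structures",
]


@dataclass
class ClusterResult:
    """gromos clustering output.

    labels: per-item 1-based cluster id (cluster 1 is the largest);
    centroids: per-cluster item index of the representative structure;
    populations: per-cluster member counts.
    """

    labels: np.ndarray
    centroids: list[int]
    populations: list[int]
    cutoff: float
    item_labels: list[str]

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def gromos_cluster(dmatrix: DistanceMatrix, cutoff: float) -> ClusterResult:
    """Cluster items of a mutual-RMSD matrix with the gromos method."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = dmatrix.values
    n = d.shape[0]
    neighbor = d <= cutoff  # includes self on the diagonal
    unassigned = np.ones(n, dtype=bool)
    raw_labels = np.zeros(n, dtype=int)
    raw_centroids: list[int] = []
    raw_pops: list[int] = []
    cluster_id = 0
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & unassigned)
        cluster_id += 1
        raw_labels[members] = cluster_id
        raw_centroids.append(center)
        raw_pops.append(int(members.size))
        unassigned[members] = False
    # renumber by decreasing population; stable on ties (discovery order)
    order = sorted(range(cluster_id), key=lambda c: (-raw_pops[c], c))
    remap = {old + 1: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in raw_labels], dtype=int)
    centroids = [raw_centroids[c] for c in order]
    populations = [raw_pops[c] for c in order]
    return ClusterResult(labels, centroids, populations, float(cutoff),
                         list(dmatrix.item_labels))


def cluster_membership_by_source(
    result: ClusterResult, source_labels: Sequence[str]
):
    """Contingency table: rows = source models, columns = cluster ids.

    Also annotates per-cluster source purity (fraction of the cluster's
    members coming from its most frequent source).
    """
    import pandas as pd

    if len(source_labels) != len(result.labels):
        raise ValueError(
            f"{len(source_labels)} source labels for {len(result.labels)} items"
        )
    df = pd.DataFrame({"source": list(source_labels), "cluster": result.labels})
    table = pd.crosstab(df["source"], df["cluster"])
    table = table.reindex(columns=range(1, result.n_clusters + 1), fill_value=0)
    purity = (table.max(axis=0) / table.sum(axis=0)).rename("purity")
    return table, purity


def extract_centroid_structures(
    traj_concat: Trajectory, result: ClusterResult
) -> list[Structure]:
    """One Structure per cluster: the frame at the cluster's centroid index."""
    structures = []
    for cluster_id, idx in enumerate(result.centroids, start=1):
        if not 0 <= idx < traj_concat.n_frames:
            raise IndexError(
                f"centroid index {idx} out of range for {traj_concat.n_frames} frames"
            )
        structures.append(
            traj_concat.frame_structure(idx, model_id=f"cluster{cluster_id}_centroid")
        )
    return structures
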