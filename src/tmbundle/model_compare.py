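"""Model-to-model comparison: mutual RMSD plus classical MDS projection.

Classical (Torgerson) multidimensional scaling is used deliberately: it is
deterministic (an eigendecomposition, no random initialization), exact for
distance matrices that are Euclidean-embeddable in the requested dimension,
and sufficient for visualizing similarity among a handful of predicted
receptor models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CorrespondenceError, GeometryError
from .geometry import DistanceMatrix, mutual_rmsd_matrix
from .structure_io import HelixSet, SelectionSpec, Structure, resolve_selection

__all__ = ["MDSEmbedding", "classical_mds", "compare_models"]

logger = logging.getLogger(__name__)


@dataclass
class MDSEmbedding:
    """Low-dimensional coordinates from classical MDS.

    coords are column-centered; eigenvalues sorted descending; stress is
    the relative residual sqrt(sum (d_ij - delta_ij)^2 / sum delta_ij^2)
    between embedded (d) and input (delta) distances.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    stress: float
    item_labels: list[str]

    def embedded_distances(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff * diff).sum(axis=2))


def _canonicalize(coords: np.ndarray) -> np.ndarray:
    """Resolve per-axis sign ambiguity: first off-origin point gets
    non-negative coordinates on every axis."""
    coords = coords.copy()
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords


def classical_mds(dmatrix: DistanceMatrix, dims: int = 2) -> MDSEmbedding:
    """Torgerson MDS: double-center -1/2 * J D^2 J and eigendecompose.

    Coordinates are the top-``dims`` eigenvectors scaled by the square root
    of their (non-negative-clamped) eigenvalues.  RMSD matrices need not be
    Euclidean, so negative eigenvalues can occur; they are clamped to zero
    with a warning.
    """
    if dims < 1:
        raise GeometryError("dims must be >= 1")
    d = dmatrix.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if np.any(eigvals[:dims] < -1e-9 * max(1.0, abs(eigvals[0]))):
        logger.warning(
            "distance matrix is not Euclidean in %d dims; clamping negative "
            "eigenvalues (min %.3g)", dims, float(eigvals.min())
        )
    lam = np.clip(eigvals[:dims], 0.0, None)
    coords = eigvecs[:, :dims] * np.sqrt(lam)[None, :]
    coords = _canonicalize(coords - coords.mean(axis=0))
    emb = MDSEmbedding(coords, eigvals, 0.0, list(dmatrix.item_labels))
    delta_sq = float((d * d).sum())
    if delta_sq == 0.0:
        emb.stress = 0.0
    else:
        resid = emb.embedded_distances() - d
        emb.stress = float(np.sqrt((resid * resid).sum() / delta_sq))
    return emb


def compare_models(
    models: Sequence[Structure],
    sel: SelectionSpec | None = None,
    helices: HelixSet | None = None,
    dims: int = 2,
) -> tuple[DistanceMatrix, MDSEmbedding]:
    """Mutual RMSD over predicted models, projected to 2D.

    The default selection is the whole-chain backbone (N, CA, C, O) —
    loops included, since model comparison is about the entire predicted
    fold; TM-only selections can be passed explicitly.
    """
    if len(models) < 2:
        raise GeometryError("need at least 2 models to compare")
    if sel is None:
        sel = SelectionSpec(atom_class="backbone")
    ref = models[0]
    ref_idx = resolve_selection(ref, sel, helices)
    ref_key = list(zip(ref.chain_ids[ref_idx], ref.residue_numbers[ref_idx],
                       ref.atom_names[ref_idx]))
    coords = []
    for m in models:
        idx = resolve_selection(m, sel, helices)
        key = list(zip(m.chain_ids[idx], m.residue_numbers[idx], m.atom_names[idx]))
        if key != ref_key:
            for a, b in zip(ref_key, key):
                if a != b:
                    raise CorrespondenceError(
                        f"model {m.model_id}: first mismatching atom "
                        f"{b} vs {a} in {ref.model_id}"
                    )
            raise CorrespondenceError(
                f"model {m.model_id}: selection size {len(key)} differs from "
                f"{len(ref_key)} in {ref.model_id}"
            )
        coords.append(m.coords[idx])
    dmatrix = mutual_rmsd_matrix(np.stack(coords), labels=[m.model_id for m in models])
    return dmatrix, classical_mds(dmatrix, dims=dims)
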