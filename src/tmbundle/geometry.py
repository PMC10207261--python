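"""Rigid superposition (Kabsch), RMSD and mutual-RMSD matrices.

This is the numeric core shared by model comparison, stability metrics and
conformational clustering.  Superposition is the closed-form SVD solution
with the determinant sign correction that excludes reflections; there is a
single code path for all callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError

__all__ = [
    "RigidTransform",
    "DistanceMatrix",
    "kabsch_superpose",
    "rmsd_fitted",
    "mutual_rmsd_matrix",
    "minimum_image",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation`` (angstroms)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


class DistanceMatrix:
    """Symmetric all-vs-all RMSD matrix with item labels."""

    def __init__(self, values: np.ndarray, item_labels: Sequence[str]) -> None:
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        if values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(item_labels) != n:
            raise ValueError("label count must match matrix size")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        self.values = values
        self.item_labels = [str(l) for l in item_labels]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.item_labels,
                     columns=self.item_labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)))


def _check_points(coords: np.ndarray, name: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise GeometryError(f"{name} must be an (n, 3) array")
    if coords.shape[0] < 3:
        raise GeometryError(f"{name} needs at least 3 points, got {coords.shape[0]}")
    return coords


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid superposition of *mobile* onto *target*.

    Returns the optimal transform and the residual RMSD in angstroms.
    Point sets must be in 1:1 correspondence.  All-collinear inputs leave
    the rotation about the line undetermined and are rejected.
    """
    mobile = _check_points(mobile, "mobile")
    target = _check_points(target, "target")
    if mobile.shape != target.shape:
        raise GeometryError(
            f"point counts differ: {mobile.shape[0]} vs {target.shape[0]}"
        )
    mob_c = mobile.mean(axis=0)
    tar_c = target.mean(axis=0)
    a = mobile - mob_c
    b = target - tar_c
    # rank check: collinear point sets have one non-trivial principal axis
    sv = np.linalg.svd(a, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    if sv[1] / scale < 1e-9:
        raise GeometryError("mobile points are collinear; rotation is ill-conditioned")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    transform = RigidTransform(rot, tar_c - rot @ mob_c)
    diff = a @ rot.T - b
    rmsd = float(np.sqrt((diff * diff).sum() / mobile.shape[0]))
    return transform, rmsd


def rmsd_fitted(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    fit_indices: np.ndarray,
    measure_indices: np.ndarray,
) -> float:
    """RMSD over *measure_indices* after superposing on *fit_indices*.

    ``frame_a`` is superposed onto ``frame_b``; the two index lists may
    differ (e.g. fit on the helix core, measure all heavy atoms).
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    fit_indices = np.asarray(fit_indices, dtype=int)
    measure_indices = np.asarray(measure_indices, dtype=int)
    if measure_indices.size == 0:
        raise GeometryError("measure index set is empty")
    transform, _ = kabsch_superpose(frame_a[fit_indices], frame_b[fit_indices])
    moved = transform.apply(frame_a[measure_indices])
    diff = moved - frame_b[measure_indices]
    return float(np.sqrt((diff * diff).sum() / measure_indices.size))


def mutual_rmsd_matrix(
    frames: Sequence[np.ndarray] | np.ndarray,
    indices: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All-vs-all Kabsch RMSD matrix over *frames* on the selected atoms.

    Each pair is fitted independently (no global reference), matching the
    mutual-RMSD protocol used for conformational clustering.  O(n^2) pairs;
    intended for frame counts up to a few thousand after striding.
    """
    arr = np.asarray(frames, dtype=float)
    if arr.ndim != 3:
        raise GeometryError("frames must be a (n_frames, n_atoms, 3) stack")
    if indices is not None:
        arr = arr[:, np.asarray(indices, dtype=int), :]
    n = arr.shape[0]
    if n < 1:
        raise GeometryError("need at least one frame")
    centered = arr - arr.mean(axis=1, keepdims=True)
    sq_norms = np.einsum("kij,kij->k", centered, centered)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                h = centered[i].T @ centered[j]
                u, s, vt = np.linalg.svd(h)
                d = np.sign(np.linalg.det(vt.T @ u.T))
                # E_min = (|a|^2 + |b|^2 - 2 * corrected trace) / n
                trace = s[0] + s[1] + d * s[2]
                msd = (sq_norms[i] + sq_norms[j] - 2.0 * trace) / arr.shape[1]
                values[i, j] = values[j, i] = np.sqrt(max(msd, 0.0))
            except np.linalg.LinAlgError as exc:
                raise GeometryError(f"SVD failed for frame pair ({i}, {j})") from exc
    if labels is None:
        labels = [str(k) for k in range(n)]
    return DistanceMatrix(values, labels)


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention for orthorhombic boxes.

    Maps each displacement component into ``[-box/2, box/2)``.
    """
    displacement = np.asarray(displacement, dtype=float)
    box = np.asarray(box, dtype=float)
    return displacement - box * np.round(displacement / box)
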