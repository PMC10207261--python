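"""Per-trajectory fold-stability descriptors.

Four descriptors, each a per-frame time series:

* heavy-atom (or any selection) RMSD against a fixed reference model;
* TM6-TM7 spacing — the inter-axis distance at the membrane midplane, the
  quantity that opens from the 7-9 A (closed) to the 13-15 A (open) range
  when the helical bundle breaks;
* an activation index in the A100 style: a linear functional of
  interhelical C-alpha distances addressed by Ballesteros-Weinstein pairs,
  with the coefficients supplied via config (they are not hardcoded here);
* sodium-site occupancy at the conserved 2.50/3.39 acidic pocket, using
  minimum-image ion-carboxylate distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError, SelectionError
from .geometry import kabsch_superpose, minimum_image, rmsd_fitted
from .structure_io import (
    BWMap,
    HelixSet,
    SelectionSpec,
    Structure,
    Trajectory,
    bw_lookup,
    resolve_selection,
)

__all__ = [
    "TimeSeries",
    "ActivationIndexSpec",
    "IonSiteSpec",
    "HelixAxis",
    "rmsd_timeseries",
    "helix_axis",
    "tm_pair_distance",
    "activation_index",
    "ion_site_occupancy",
]


@dataclass
class TimeSeries:
    """Per-frame metric values with their time stamps (ns)."""

    times: np.ndarray
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be increasing")

    def __len__(self) -> int:
        return self.times.size

    def final_window_mean(self, fraction: float = 0.2) -> float:
        """Mean over the trailing *fraction* of frames (plateau estimate)."""
        n = max(1, int(round(self.times.size * fraction)))
        return float(self.values[-n:].mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ns": self.times, self.metric_name: self.values})


@dataclass(frozen=True)
class ActivationIndexSpec:
    """Linear functional over interhelical C-alpha distances.

    ``terms`` maps BW label pairs to coefficients in 1/angstrom; the value
    per frame is ``intercept + sum coeff * |CA_i - CA_j|``.  By convention
    values below a user-chosen threshold indicate inactive-like
    conformations; the coefficient set is supplied by the user (an editable
    template ships with the CLI) and is never baked in.
    """

    terms: tuple[tuple[tuple[str, str], float], ...] = ()
    intercept: float = 0.0
    distance_atom: str = "CA"

    def __post_init__(self) -> None:
        pairs = [p for p, _ in self.terms]
        if len(set(map(frozenset, pairs))) != len(pairs):
            raise ValueError("BW pairs in activation index must be distinct")
        if not all(np.isfinite(c) for _, c in self.terms):
            raise ValueError("coefficients must be finite")
        if self.distance_atom != "CA":
            raise ValueError("only CA-based distances are supported")


@dataclass(frozen=True)
class IonSiteSpec:
    """The conserved class A sodium pocket, parameterized.

    Defaults describe the D2.50 / E3.39 acidic pair with its carboxylate
    oxygens and a 3.0 A sodium-oxygen contact cutoff (typical Na+
    coordination distance).
    """

    coordinating_positions: tuple[str, ...] = ("2.50", "3.39")
    coordinating_atoms: tuple[str, ...] = ("OD1", "OD2", "OE1", "OE2")
    contact_cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")


@dataclass(frozen=True)
class HelixAxis:
    """A helix axis: a point on the line and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        point = np.asarray(self.point, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(direction), 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "direction", direction)

    def at_z(self, z: float) -> np.ndarray:
        """Point on the axis with the given z; falls back to the centroid
        for (near-)horizontal axes."""
        if abs(self.direction[2]) < 1e-6:
            return self.point
        t = (z - self.point[2]) / self.direction[2]
        return self.point + t * self.direction


def rmsd_timeseries(
    traj: Trajectory,
    reference: Structure,
    fit_sel: SelectionSpec,
    measure_sel: SelectionSpec | None = None,
    helices: HelixSet | None = None,
) -> TimeSeries:
    """RMSD of every frame against a fixed reference structure.

    Fitting and measuring selections may differ (fit on the stable TM core,
    measure all heavy atoms).  The reference is typically the starting
    predictor model rather than frame 0, so drift during early relaxation
    is visible.
    """
    fit_idx_ref = resolve_selection(reference, fit_sel, helices)
    fit_idx_trj = resolve_selection(traj.topology, fit_sel, helices)
    if measure_sel is None:
        measure_sel = fit_sel
    meas_idx_ref = resolve_selection(reference, measure_sel, helices)
    meas_idx_trj = resolve_selection(traj.topology, measure_sel, helices)
    if fit_idx_ref.size != fit_idx_trj.size or meas_idx_ref.size != meas_idx_trj.size:
        raise SelectionError(
            "selection resolves to different atom counts on reference and trajectory"
        )
    values = np.empty(traj.n_frames)
    ref_fit = reference.coords[fit_idx_ref]
    ref_meas = reference.coords[meas_idx_ref]
    for k in range(traj.n_frames):
        frame = traj.frames[k]
        transform, _ = kabsch_superpose(frame[fit_idx_trj], ref_fit)
        diff = transform.apply(frame[meas_idx_trj]) - ref_meas
        values[k] = np.sqrt((diff * diff).sum() / meas_idx_trj.size)
    return TimeSeries(traj.times, values, "rmsd_A")


def helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Axis through helix C-alpha positions, oriented toward +z
    (intracellular -> extracellular).

    Direction: for every consecutive point triple the chord bisector
    points at the axis, and cross products of successive bisectors are
    exactly parallel to the axis of an ideal helix (independent of its
    twist); these are averaged.  Point: the points projected onto the
    plane perpendicular to the direction lie on a circle whose
    least-squares center, lifted back along the axis, anchors it.  A plain
    principal-component line is the fallback for (near-)straight input.
    """
    ca_coords = np.asarray(ca_coords, dtype=float)
    if ca_coords.ndim != 2 or ca_coords.shape[1] != 3:
        raise GeometryError("ca_coords must be (m, 3)")
    if ca_coords.shape[0] < 6:
        raise GeometryError(
            f"need at least 6 CA positions for a helix axis, got {ca_coords.shape[0]}"
        )
    centroid = ca_coords.mean(axis=0)
    centered = ca_coords - centroid
    scale = np.abs(centered).max() or 1.0

    bisectors = (ca_coords[:-2] - ca_coords[1:-1]) + (ca_coords[2:] - ca_coords[1:-1])
    crosses = np.cross(bisectors[:-1], bisectors[1:])
    norms = np.linalg.norm(crosses, axis=1)
    good = norms > 1e-9 * scale**2
    if good.sum() >= 2:
        units = crosses[good] / norms[good][:, None]
        units[units @ units[0] < 0] *= -1.0
        direction = units.mean(axis=0)
        direction /= np.linalg.norm(direction)
    else:
        # straight or degenerate: principal axis of the point cloud
        _, _, vt = np.linalg.svd(centered)
        direction = vt[0]

    if direction[2] < 0 or (direction[2] == 0 and direction[np.argmax(np.abs(direction))] < 0):
        direction = -direction

    # anchor point: circle fit (Kasa) in the plane perpendicular to the axis
    basis = np.linalg.svd(np.eye(3) - np.outer(direction, direction))[0][:, :2]
    q = centered @ basis
    spread = np.abs(q).max()
    if spread < 1e-9 * scale:
        center_2d = q.mean(axis=0)
    else:
        a_mat = np.column_stack([2.0 * q, np.ones(len(q))])
        rhs = (q * q).sum(axis=1)
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        center_2d = sol[:2]
    axial = centered @ direction
    point = centroid + basis @ center_2d + axial.mean() * direction
    return HelixAxis(point, direction / np.linalg.norm(direction))


def _helix_ca_indices(topology: Structure, helices: HelixSet, name: str) -> np.ndarray:
    if name not in helices:
        raise SelectionError(f"helix {name!r} not defined in HelixSet")
    sel = SelectionSpec(atom_class="ca", helices=(name,))
    return resolve_selection(topology, sel, helices)


def tm_pair_distance(
    traj: Trajectory,
    helices: HelixSet,
    pair: tuple[str, str] = ("TM6", "TM7"),
    mode: str = "axis_midplane",
) -> TimeSeries:
    """Per-frame spacing between two TM helices.

    ``axis_midplane`` (default): fit each helix axis per frame and measure
    the distance between the two axes evaluated at the membrane midplane
    (the box z-center) — appropriate for the splaying motion that separates
    TM6 from TM7.  ``ca_com``: distance between the C-alpha centroids of
    the cytoplasmic (lower-z) halves of each helix.
    """
    if mode not in ("axis_midplane", "ca_com"):
        raise ValueError(f"unknown mode {mode!r}")
    idx_a = _helix_ca_indices(traj.topology, helices, pair[0])
    idx_b = _helix_ca_indices(traj.topology, helices, pair[1])
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        ca_a = traj.frames[k][idx_a]
        ca_b = traj.frames[k][idx_b]
        if mode == "axis_midplane":
            z_mid = traj.box[k][2] / 2.0
            pa = helix_axis(ca_a).at_z(z_mid)
            pb = helix_axis(ca_b).at_z(z_mid)
            values[k] = np.linalg.norm(pa - pb)
        else:
            half_a = ca_a[np.argsort(ca_a[:, 2])[: max(3, len(ca_a) // 2)]]
            half_b = ca_b[np.argsort(ca_b[:, 2])[: max(3, len(ca_b) // 2)]]
            values[k] = np.linalg.norm(half_a.mean(axis=0) - half_b.mean(axis=0))
    return TimeSeries(traj.times, values, f"{pair[0]}_{pair[1]}_distance_A")


def activation_index(
    traj: Trajectory, bwmap: BWMap, spec: ActivationIndexSpec
) -> TimeSeries:
    """A100-style activation descriptor: linear combination of interhelical
    CA distances addressed by BW label pairs."""
    topo = traj.topology
    pair_indices: list[tuple[int, int, float]] = []
    for (label_i, label_j), coeff in spec.terms:
        idx = []
        for label in (label_i, label_j):
            try:
                resnum = bw_lookup(bwmap, label)
            except KeyError as exc:
                raise SelectionError(f"BW pair ({label_i}, {label_j}): {exc}") from exc
            hits = np.flatnonzero(
                (topo.residue_numbers == resnum)
                & (topo.atom_names.astype(str) == spec.distance_atom)
            )
            if hits.size == 0:
                raise SelectionError(
                    f"BW pair ({label_i}, {label_j}): residue {resnum} has no "
                    f"{spec.distance_atom} atom"
                )
            idx.append(int(hits[0]))
        pair_indices.append((idx[0], idx[1], float(coeff)))
    values = np.full(traj.n_frames, float(spec.intercept))
    for i, j, coeff in pair_indices:
        d = np.linalg.norm(traj.frames[:, i, :] - traj.frames[:, j, :], axis=1)
        values += coeff * d
    return TimeSeries(traj.times, values, "activation_index")


def ion_site_occupancy(
    traj: Trajectory,
    bwmap: BWMap,
    site: IonSiteSpec = IonSiteSpec(),
    ion_indices: np.ndarray | None = None,
) -> tuple[float, float | None, TimeSeries]:
    """Sodium occupancy of the 2.50/3.39 pocket.

    A frame is occupied iff any selected ion lies within
    ``site.contact_cutoff`` of any coordinating carboxylate oxygen
    (minimum-image convention; the protein is assumed whole).  Returns the
    occupancy fraction, the time of first binding (or None) and the
    per-frame minimum ion-site distance series.
    """
    topo = traj.topology
    if ion_indices is None:
        ion_indices = np.flatnonzero(topo.is_ion())
    ion_indices = np.asarray(ion_indices, dtype=int)
    try:
        site_resnums = [bw_lookup(bwmap, label) for label in site.coordinating_positions]
    except KeyError as exc:
        raise SelectionError(f"ion-site position not in BW map: {exc}") from exc
    coord_mask = np.isin(topo.residue_numbers, site_resnums) & np.isin(
        topo.atom_names.astype(str), site.coordinating_atoms
    )
    coord_idx = np.flatnonzero(coord_mask)
    if coord_idx.size == 0:
        raise SelectionError(
            f"no coordinating atoms {site.coordinating_atoms} found on residues "
            f"{site_resnums} (site residues mutated or missing?)"
        )
    min_dist = np.full(traj.n_frames, np.inf)
    if ion_indices.size > 0:
        for k in range(traj.n_frames):
            ions = traj.frames[k][ion_indices]
            oxy = traj.frames[k][coord_idx]
            disp = ions[:, None, :] - oxy[None, :, :]
            disp = minimum_image(disp, traj.box[k])
            min_dist[k] = np.sqrt((disp * disp).sum(axis=2)).min()
    occupied = min_dist <= site.contact_cutoff
    occupancy = float(occupied.mean()) if traj.n_frames else 0.0
    first_time = float(traj.times[np.argmax(occupied)]) if occupied.any() else None
    series = TimeSeries(traj.times, min_dist, "ion_site_min_distance_A")
    return occupancy, first_time, series
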