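"""Water permeation detection through the receptor interior.

The simulation box is split along z into an intracellular compartment
(below ``z_lower``), an extracellular compartment (above ``z_upper``) and
a membrane slab in between.  Inside the slab, positions within a cylinder
around the helical bundle are "through the receptor" (TM); the rest of the
slab is BULK (around the protein, i.e. membrane/solvent).  A permeation
event is one maximal passage of a water molecule from one compartment to
the other that visits TM at least once and never touches BULK in between:
waters that go around the protein are not counted.

Periodic wraps need no special casing in the state machine: a wrap
teleports a particle between deep IC and deep EC without ever visiting the
slab interior, so the through-TM requirement already discards it.  The
:func:`unwrap_z` utility is provided for continuous single-particle
z-tracks (plots, diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError
from .geometry import minimum_image
from .structure_io import HelixSet, SelectionSpec, Trajectory, resolve_selection

__all__ = [
    "CompartmentSpec",
    "PermeationEvent",
    "unwrap_z",
    "assign_region",
    "detect_permeations",
    "permeation_summary",
    "IC", "TM", "EC", "BULK",
]

IC, TM, EC, BULK = "IC", "TM", "EC", "BULK"


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry of the IC / membrane-slab / EC partition.

    ``cylinder_center_xy`` is either a fixed (x, y) pair or the string
    ``"bundle-centroid"``, meaning the per-frame xy centroid of the TM
    C-alpha atoms.  Defaults: slab of +-20 A about the box z-center is
    applied by the caller (see :func:`default_compartments`); cylinder
    radius 12 A.
    """

    z_lower: float
    z_upper: float
    cylinder_center_xy: tuple[float, float] | str = "bundle-centroid"
    cylinder_radius: float = 12.0

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValueError("z_lower must be below z_upper")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be positive")


def default_compartments(box_z: float, half_slab: float = 20.0,
                         radius: float = 12.0) -> CompartmentSpec:
    """Slab of +-half_slab about the box z-center, bundle-centered cylinder."""
    center = box_z / 2.0
    return CompartmentSpec(center - half_slab, center + half_slab,
                           "bundle-centroid", radius)


@dataclass(frozen=True)
class PermeationEvent:
    """One complete IC<->EC crossing of a single water molecule."""

    water_id: int
    entry_frame: int
    exit_frame: int
    direction: str  # "IC->EC" or "EC->IC"

    def __post_init__(self) -> None:
        if self.entry_frame > self.exit_frame:
            raise ValueError("entry_frame must be <= exit_frame")
        if self.direction not in ("IC->EC", "EC->IC"):
            raise ValueError(f"bad direction {self.direction!r}")


def unwrap_z(z_series: np.ndarray, box_z: np.ndarray | float) -> np.ndarray:
    """Remove periodic jumps from one particle's wrapped z-track.

    Whenever a successive difference exceeds half the box, a full box
    length is added or subtracted, yielding a continuous trajectory.
    """
    z = np.asarray(z_series, dtype=float)
    box = np.broadcast_to(np.asarray(box_z, dtype=float), z.shape)
    if z.size == 0:
        return z.copy()
    dz = np.diff(z)
    shift = -box[1:] * np.round(dz / box[1:])
    out = z.copy()
    out[1:] += np.cumsum(shift)
    return out


def assign_region(xy: np.ndarray, z: float, spec: CompartmentSpec,
                  center_xy: np.ndarray | None = None) -> str:
    """Classify one wrapped position as IC, EC, TM or BULK."""
    if z < spec.z_lower:
        return IC
    if z > spec.z_upper:
        return EC
    if center_xy is None:
        if isinstance(spec.cylinder_center_xy, str):
            raise ValueError(
                "spec uses 'bundle-centroid'; pass center_xy explicitly"
            )
        center_xy = np.asarray(spec.cylinder_center_xy, dtype=float)
    r = np.linalg.norm(np.asarray(xy, dtype=float) - center_xy)
    return TM if r <= spec.cylinder_radius else BULK


def _cylinder_centers(traj: Trajectory, spec: CompartmentSpec,
                      helices: HelixSet | None) -> np.ndarray:
    if not isinstance(spec.cylinder_center_xy, str):
        c = np.asarray(spec.cylinder_center_xy, dtype=float)
        return np.repeat(c[None, :], traj.n_frames, axis=0)
    if spec.cylinder_center_xy != "bundle-centroid":
        raise ValueError(f"unknown cylinder center {spec.cylinder_center_xy!r}")
    sel = SelectionSpec(
        atom_class="ca",
        helices=tuple(helices.names()) if helices is not None else None,
    )
    ca_idx = resolve_selection(traj.topology, sel, helices)
    return traj.frames[:, ca_idx, :2].mean(axis=1)


def detect_permeations(
    traj: Trajectory,
    spec: CompartmentSpec,
    water_indices: np.ndarray | None = None,
    helices: HelixSet | None = None,
) -> list[PermeationEvent]:
    """Detect complete water crossings through the receptor.

    Waters are tracked by their oxygen atom only.  Per water, a state
    machine over the region sequence emits one event per maximal
    IC->(TM...)->EC passage (or the reverse); any BULK visit between the
    two compartments disqualifies the passage (the water went around the
    protein, not through it).  Re-entries after a completed passage can
    produce further events.

    ``entry_frame`` is the last frame spent in the origin compartment
    before the passage; ``exit_frame`` the first frame in the destination.
    """
    topo = traj.topology
    if water_indices is None:
        water_mask = topo.is_water() & (topo.elements.astype(str) == "O")
        water_indices = np.flatnonzero(water_mask)
    water_indices = np.asarray(water_indices, dtype=int)
    if water_indices.size == 0:
        raise SelectionError("no water oxygen atoms selected")

    centers = _cylinder_centers(traj, spec, helices)
    events: list[PermeationEvent] = []
    for atom_idx in water_indices:
        water_id = int(topo.residue_numbers[atom_idx])
        origin: str | None = None
        origin_frame = 0
        passed_tm = False
        tainted = False
        for k in range(traj.n_frames):
            pos = traj.frames[k, atom_idx]
            region = assign_region(pos[:2], pos[2], spec, centers[k])
            if region in (IC, EC):
                if (origin is not None and region != origin
                        and passed_tm and not tainted):
                    direction = "IC->EC" if origin == IC else "EC->IC"
                    events.append(PermeationEvent(water_id, origin_frame, k, direction))
                origin = region
                origin_frame = k
                passed_tm = False
                tainted = False
            elif region == TM:
                passed_tm = True
            else:  # BULK
                tainted = True
    events.sort(key=lambda e: (e.exit_frame, e.entry_frame, e.water_id))
    return events


def permeation_summary(events: Sequence[PermeationEvent], traj: Trajectory) -> dict:
    """Counts per direction plus a rate normalized per 100 ns."""
    n_ic_ec = sum(1 for e in events if e.direction == "IC->EC")
    n_ec_ic = len(events) - n_ic_ec
    duration = traj.duration_ns
    rate = len(events) / (duration / 100.0) if duration > 0 else 0.0
    return {
        "total": len(events),
        "IC->EC": n_ic_ec,
        "EC->IC": n_ec_ic,
        "duration_ns": duration,
        "rate_per_100ns": rate,
    }


def events_to_frame(events: Sequence[PermeationEvent]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "water_id": e.water_id,
                "entry_frame": e.entry_frame,
                "exit_frame": e.exit_frame,
                "direction": e.direction,
            }
            for e in events
        ],
        columns=["water_id", "entry_frame", "exit_frame", "direction"],
    )
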