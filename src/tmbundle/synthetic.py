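"""Synthetic 7-helix transmembrane bundles with scripted ground truth.

This module is the statistical stand-in for real MD trajectories: it
builds idealized poly-alanine helical bundles in a periodic box and
animates them with *scripted* events — rigid drift, TM6-TM7 splaying
schedules, water permeation paths (optionally forced through a periodic
wrap), non-permeating distractor waters, and sodium binding/unbinding at
the 2.50/3.39 pocket.  Every planted quantity is known exactly, so each
analysis operation can be tested for parameter recovery.

Geometry: ideal alpha-helix parameters (1.5 A rise and 100 deg twist per
residue), helices placed on a circle and running antiparallel along z,
short loop connectors between consecutive helices, and pseudo-carboxylate
oxygens (OD1/OD2, OE1/OE2) planted at the conserved acidic positions 2.50
and 3.39 so the sodium-pocket analysis has something to coordinate to.
No force field, no thermodynamics: motion is purely kinematic plus
optional Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, GeometryError
from .structure_io import BWMap, HelixSet, SelectionSpec, Structure, Trajectory, resolve_selection

__all__ = [
    "BundleSpec",
    "SplayEvent",
    "PermeationPlan",
    "DistractorPlan",
    "EventSchedule",
    "make_bundle",
    "make_trajectory",
    "make_model_set",
]

CA_HELIX_RADIUS = 2.3  # A, distance of CA from the helix axis in an ideal helix


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of the synthetic transmembrane bundle.

    Defaults emulate the simulated receptor system: seven helices in a
    100 x 100 x 120 A box, standard alpha-helix rise/twist.
    """

    n_helices: int = 7
    residues_per_helix: int = 25
    bundle_radius: float = 11.0
    helix_rise: float = 1.5
    helix_twist_deg: float = 100.0
    box: tuple[float, float, float] = (100.0, 100.0, 120.0)
    loop_residues: int = 4

    def __post_init__(self) -> None:
        if self.n_helices < 2:
            raise ConfigError("need at least 2 helices")
        if any(b <= 0 for b in self.box):
            raise ConfigError("box lengths must be positive")
        if self.residues_per_helix < HelixSet.MIN_HELIX_RESIDUES:
            raise ConfigError("helices must have at least 6 residues")
        # neighboring helix axes closer than ~4 A would interpenetrate
        min_sep = 2.0 * self.bundle_radius * math.sin(math.pi / self.n_helices)
        if min_sep < 4.0:
            raise ConfigError(
                f"bundle_radius {self.bundle_radius} A places neighboring helix "
                f"axes only {min_sep:.1f} A apart (steric overlap)"
            )


@dataclass(frozen=True)
class SplayEvent:
    """Linear schedule for the axis distance of a helix pair (A)."""

    pair: tuple[str, str] = ("TM6", "TM7")
    start_frame: int = 0
    end_frame: int = 0
    start_distance: float = 8.0
    end_distance: float = 14.0


@dataclass(frozen=True)
class PermeationPlan:
    """One scripted complete water crossing.

    ``via_wrap`` routes the approach through the periodic z boundary: the
    water first drifts out of the far compartment across the box edge and
    then traverses the slab, exercising PBC handling in the detector.
    """

    start_frame: int
    duration: int
    direction: str = "IC->EC"
    via_wrap: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("IC->EC", "EC->IC"):
            raise ConfigError(f"bad direction {self.direction!r}")
        if self.duration < 1:
            raise ConfigError("duration must be >= 1")
        if self.via_wrap and self.duration < 8:
            raise ConfigError("via_wrap passages need duration >= 8 frames")


@dataclass(frozen=True)
class DistractorPlan:
    """A water that must NOT be counted.

    kinds: ``bounce`` — enters the channel from IC and returns;
    ``around`` — crosses IC->EC outside the bundle cylinder (through
    "membrane"/bulk); ``wrap_drift`` — drifts across the periodic z
    boundary in bulk without ever visiting the channel.
    """

    kind: str = "bounce"
    start_frame: int = 0
    duration: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("bounce", "around", "wrap_drift"):
            raise ConfigError(f"unknown distractor kind {self.kind!r}")
        if self.duration < 2:
            raise ConfigError("duration must be >= 2")


@dataclass(frozen=True)
class EventSchedule:
    """Everything that happens in a scripted trajectory."""

    splay: tuple[SplayEvent, ...] = ()
    permeations: tuple[PermeationPlan, ...] = ()
    distractors: tuple[DistractorPlan, ...] = ()
    ion_binding: tuple[tuple[int, bool], ...] = ()
    rigid_drift: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")

    def validate(self, n_frames: int) -> None:
        for p in self.permeations:
            if p.start_frame < 0 or p.start_frame + p.duration > n_frames:
                raise ConfigError(
                    f"permeation at frame {p.start_frame} (+{p.duration}) exceeds "
                    f"{n_frames} frames"
                )
        for d in self.distractors:
            if d.start_frame < 0 or d.start_frame + d.duration > n_frames:
                raise ConfigError("distractor schedule exceeds trajectory length")
        for s in self.splay:
            if not 0 <= s.start_frame <= s.end_frame < max(n_frames, 1):
                raise ConfigError("splay schedule exceeds trajectory length")
        for frame, _ in self.ion_binding:
            if not 0 <= frame < n_frames:
                raise ConfigError("ion binding step outside trajectory")


def _helix_frame_points(spec: BundleSpec, helix: int, n_res: int) -> np.ndarray:
    """CA curve parameter -> xyz for one helix (local helix coordinates)."""
    # local curve: axis along z through origin, CA at CA_HELIX_RADIUS
    t = np.arange(n_res, dtype=float)
    return t


def make_bundle(spec: BundleSpec = BundleSpec()) -> tuple[Structure, HelixSet, BWMap]:
    """Build the idealized bundle.

    Helices TM1..TMn sit on a circle of ``bundle_radius`` around the box
    center, run antiparallel along z, and are joined by short loop
    residues.  Residue numbering is sequential.  The returned BWMap labels
    every helix residue ``h.(50 + offset from the helix midpoint)``; the
    midpoint residue of helix h is ``h.50``.  Pseudo-carboxylate oxygens
    are attached at positions 2.50 (as ASP) and 3.39 (as GLU) when those
    helices exist, pointing into the inter-helix pocket.
    """
    n_res = spec.residues_per_helix
    twist = math.radians(spec.helix_twist_deg)
    box_center = np.array(spec.box) / 2.0
    helix_len_z = (n_res - 1) * spec.helix_rise

    atom_names: list[str] = []
    elements: list[str] = []
    residue_numbers: list[int] = []
    residue_names: list[str] = []
    chain_ids: list[str] = []
    coords: list[np.ndarray] = []
    ranges: dict[str, tuple[int, int]] = {}
    bw_entries: dict[int, str] = {}

    def curve_point(axis_xy: np.ndarray, ascending: bool, t: float,
                    radius: float = CA_HELIX_RADIUS) -> np.ndarray:
        ang = twist * t
        z_local = t * spec.helix_rise
        if not ascending:
            z_local = helix_len_z - z_local
        return np.array([
            axis_xy[0] + radius * math.cos(ang),
            axis_xy[1] + radius * math.sin(ang),
            box_center[2] - helix_len_z / 2.0 + z_local,
        ])

    def add_atom(name: str, element: str, resnum: int, resname: str,
                 pos: np.ndarray) -> None:
        atom_names.append(name)
        elements.append(element)
        residue_numbers.append(resnum)
        residue_names.append(resname)
        chain_ids.append("A")
        coords.append(pos)

    resnum = 0
    helix_axes_xy: list[np.ndarray] = []
    last_helix_end: np.ndarray | None = None
    mid_offset = n_res // 2
    site_residues: dict[str, int] = {}

    for h in range(spec.n_helices):
        phi = 2.0 * math.pi * h / spec.n_helices
        axis_xy = box_center[:2] + spec.bundle_radius * np.array(
            [math.cos(phi), math.sin(phi)]
        )
        helix_axes_xy.append(axis_xy)
        ascending = h % 2 == 0
        start_resnum = resnum + 1
        for i in range(n_res):
            resnum += 1
            ca = curve_point(axis_xy, ascending, float(i))
            n_pos = curve_point(axis_xy, ascending, i - 0.38, radius=1.65)
            c_pos = curve_point(axis_xy, ascending, i + 0.42, radius=1.70)
            o_dir = c_pos[:2] - axis_xy
            o_pos = c_pos + np.array([*(0.45 * o_dir / np.linalg.norm(o_dir)), 1.05])
            cb_dir = (ca[:2] - axis_xy) / np.linalg.norm(ca[:2] - axis_xy)
            cb_pos = ca + np.array([*(1.2 * cb_dir), 0.6])
            add_atom("N", "N", resnum, "ALA", n_pos)
            add_atom("CA", "C", resnum, "ALA", ca)
            add_atom("C", "C", resnum, "ALA", c_pos)
            add_atom("O", "O", resnum, "ALA", o_pos)
            add_atom("CB", "C", resnum, "ALA", cb_pos)
            bw_entries[resnum] = f"{h + 1}.{50 + i - mid_offset}"
            if f"{h + 1}.{50 + i - mid_offset}" == "2.50":
                site_residues["2.50"] = resnum
            if f"{h + 1}.{50 + i - mid_offset}" == "3.39":
                site_residues["3.39"] = resnum
        ranges[f"TM{h + 1}"] = (start_resnum, resnum)
        helix_start_ca = curve_point(axis_xy, ascending, 0.0)
        helix_end_ca = curve_point(axis_xy, ascending, float(n_res - 1))
        if last_helix_end is not None and spec.loop_residues > 0:
            # loop connecting previous helix end to this helix start,
            # bulging slightly outward so loop atoms sit off the helix axes
            start, end = last_helix_end, helix_start_ca
            for j in range(spec.loop_residues):
                resnum += 1
                frac = (j + 1) / (spec.loop_residues + 1)
                ca = start + frac * (end - start)
                out_dir = ca[:2] - box_center[:2]
                out_norm = np.linalg.norm(out_dir)
                if out_norm > 1e-9:
                    ca = ca + np.array([*(2.0 * out_dir / out_norm), 0.0])
                zsign = 1.0 if ca[2] > box_center[2] else -1.0
                ca = ca + np.array([0.0, 0.0, zsign * 2.0])
                add_atom("N", "N", resnum, "GLY", ca + np.array([-0.9, 0.4, 0.3]))
                add_atom("CA", "C", resnum, "GLY", ca)
                add_atom("C", "C", resnum, "GLY", ca + np.array([0.9, 0.5, -0.3]))
                add_atom("O", "O", resnum, "GLY", ca + np.array([1.1, 1.4, -0.5]))
        last_helix_end = helix_end_ca

    structure_coords = np.array(coords)

    # pseudo-carboxylate oxygens at the sodium pocket (helices 2 and 3)
    if "2.50" in site_residues and "3.39" in site_residues:
        pocket = (helix_axes_xy[1] + helix_axes_xy[2]) / 2.0
        names_res = ((site_residues["2.50"], "ASP", ("OD1", "OD2"), helix_axes_xy[1]),
                     (site_residues["3.39"], "GLU", ("OE1", "OE2"), helix_axes_xy[2]))
        # both side chains converge on a single pocket point between the
        # two helices (as D2.50/E3.39 do around a bound sodium), so the
        # oxygens share one z level midway between the two anchor residues
        z_levels = []
        for site_resnum, *_ in names_res:
            mask = np.array(residue_numbers) == site_resnum
            ca_idx = int(np.flatnonzero(
                mask & (np.array(atom_names, dtype=object) == "CA"))[0])
            z_levels.append(structure_coords[ca_idx][2])
        z_site = float(np.mean(z_levels))
        extra: list[tuple[str, int, str, np.ndarray]] = []
        for site_resnum, resname, oxygens, axis_xy in names_res:
            mask = np.array(residue_numbers) == site_resnum
            for i in np.flatnonzero(mask):
                residue_names[i] = resname
            toward = pocket - axis_xy
            toward = toward / np.linalg.norm(toward)
            base = np.array([*(axis_xy + 3.2 * toward), z_site])
            for o_name, dz in zip(oxygens, (0.6, -0.6)):
                extra.append((o_name, site_resnum, resname,
                              base + np.array([0.0, 0.0, dz])))
        for o_name, site_resnum, resname, pos in extra:
            add_atom(o_name, "O", site_resnum, resname, pos)
        structure_coords = np.array(coords)

    structure = Structure(
        atom_names, elements, residue_numbers, residue_names, chain_ids,
        structure_coords, model_id="synthetic_bundle",
    )
    return structure, HelixSet(ranges), BWMap(bw_entries)


def _helix_atom_indices(structure: Structure, helices: HelixSet, name: str) -> np.ndarray:
    resnums = np.array(sorted(helices.residues(name)))
    return np.flatnonzero(np.isin(structure.residue_numbers, resnums))


def _water_z_path(plan: PermeationPlan, n_frames: int, z_center: float,
                  box_z: float) -> np.ndarray:
    """Scripted (possibly unwrapped) z per frame for one permeating water."""
    park_low, park_high = z_center - 35.0, z_center + 35.0
    lo, hi = z_center - 28.0, z_center + 28.0
    z = np.empty(n_frames)
    f0, f1 = plan.start_frame, plan.start_frame + plan.duration - 1
    if not plan.via_wrap:
        a, b = (park_low, park_high) if plan.direction == "IC->EC" else (park_high, park_low)
        a_t, b_t = (lo, hi) if plan.direction == "IC->EC" else (hi, lo)
        z[:f0] = a
        z[f0:f1 + 1] = np.linspace(a_t, b_t, plan.duration)
        z[f1 + 1:] = b
    elif plan.direction == "IC->EC":
        # start parked in EC, drift up across the box edge (wraps to deep
        # IC), then climb through the channel back into EC
        z[:f0] = park_high
        z[f0:f1 + 1] = np.linspace(park_high, box_z + hi, plan.duration)
        z[f1 + 1:] = box_z + park_high
    else:
        z[:f0] = park_low
        z[f0:f1 + 1] = np.linspace(park_low, -box_z + lo, plan.duration)
        z[f1 + 1:] = -box_z + park_low
    return z


def _distractor_z_xy(plan: DistractorPlan, n_frames: int, center: np.ndarray,
                     box_z: float, cylinder_radius: float = 12.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    z_center = box_z / 2.0
    z = np.empty(n_frames)
    xy = np.repeat(center[None, :2], n_frames, axis=0)
    f0, f1 = plan.start_frame, plan.start_frame + plan.duration - 1
    if plan.kind == "bounce":
        z[:f0] = z_center - 35.0
        half = max(1, plan.duration // 2)
        down_len = plan.duration - half
        z[f0:f0 + half] = np.linspace(z_center - 35.0, z_center, half)
        z[f0 + half:f1 + 1] = np.linspace(z_center, z_center - 35.0, down_len)
        z[f1 + 1:] = z_center - 35.0
    elif plan.kind == "around":
        z[:f0] = z_center - 35.0
        z[f0:f1 + 1] = np.linspace(z_center - 28.0, z_center + 28.0, plan.duration)
        z[f1 + 1:] = z_center + 35.0
        xy = xy + np.array([cylinder_radius + 8.0, 0.0])
    else:  # wrap_drift: climbs across the periodic boundary in bulk
        z[:f0] = z_center + 30.0
        z[f0:f1 + 1] = np.linspace(z_center + 30.0, box_z + 10.0, plan.duration)
        z[f1 + 1:] = box_z + 10.0
    return z, xy


def make_trajectory(
    structure: Structure,
    helices: HelixSet,
    schedule: EventSchedule = EventSchedule(),
    n_frames: int = 100,
    dt_ns: float = 5.0,
) -> Trajectory:
    """Animate the bundle according to *schedule*.

    Deterministic for a fixed seed.  Splaying rigidly displaces each helix
    of the named pair along the line joining their axes so the axis
    distance follows the scheduled linear ramp exactly; scripted waters
    are single-oxygen residues following their planned z paths (wrapped
    into the box, exercising PBC); the sodium ion toggles between a bulk
    parking spot and the carboxylate-oxygen midpoint; Gaussian noise of
    ``noise_sigma`` is added to every atom of every frame.
    """
    schedule.validate(n_frames)
    box = np.array([100.0, 100.0, 120.0])
    # infer the box from the structure's spread when it differs from default
    span = structure.coords.max(axis=0) - structure.coords.min(axis=0)
    if np.any(span > box):
        raise ConfigError("structure does not fit the 100x100x120 A box")
    box_z = box[2]
    z_center = box_z / 2.0
    center = structure.coords.mean(axis=0)

    rng = np.random.default_rng(schedule.seed)
    n_protein = structure.n_atoms

    # --- scripted waters -------------------------------------------------
    water_tracks: list[np.ndarray] = []  # wrapped (n_frames, 3) per water
    next_resnum = int(structure.residue_numbers.max()) + 1
    extra_names, extra_elems, extra_resnums, extra_resnames, extra_chains = \
        [], [], [], [], []

    def new_water(track: np.ndarray) -> None:
        nonlocal next_resnum
        extra_names.append("O")
        extra_elems.append("O")
        extra_resnums.append(next_resnum)
        extra_resnames.append("HOH")
        extra_chains.append("W")
        next_resnum += 1
        water_tracks.append(track)

    for i, plan in enumerate(schedule.permeations):
        z_path = _water_z_path(plan, n_frames, z_center, box_z) % box_z
        # xy inside the bundle cylinder, offset per water to avoid overlap
        ang = 2.0 * math.pi * i / max(len(schedule.permeations), 1)
        xy = center[:2] + 2.0 * np.array([math.cos(ang), math.sin(ang)])
        track = np.column_stack([np.full(n_frames, xy[0]),
                                 np.full(n_frames, xy[1]), z_path])
        new_water(track)
    for plan in schedule.distractors:
        z_path, xy = _distractor_z_xy(plan, n_frames, center, box_z)
        track = np.column_stack([xy[:, 0], xy[:, 1], z_path % box_z])
        new_water(track)
    for track in water_tracks:
        if np.any(track[:, :2] < 0) or np.any(track[:, :2] > box[:2]):
            raise ConfigError("scripted water path exits the box in xy")

    # --- ion -------------------------------------------------------------
    has_ion = len(schedule.ion_binding) > 0
    site_oxy_idx = np.flatnonzero(
        np.isin(structure.atom_names.astype(str), ("OD1", "OD2", "OE1", "OE2"))
    )
    if has_ion and site_oxy_idx.size == 0:
        raise ConfigError("ion schedule given but bundle has no pocket oxygens")
    bound = np.zeros(n_frames, dtype=bool)
    if has_ion:
        steps = sorted(schedule.ion_binding)
        state = False
        si = 0
        for k in range(n_frames):
            while si < len(steps) and steps[si][0] <= k:
                state = steps[si][1]
                si += 1
            bound[k] = state
    ion_park = np.array([10.0, 10.0, 10.0])

    # --- topology with waters/ion appended -------------------------------
    names = list(structure.atom_names) + extra_names
    elems = list(structure.elements) + extra_elems
    resnums = list(structure.residue_numbers) + extra_resnums
    resnames = list(structure.residue_names) + extra_resnames
    chains = list(structure.chain_ids) + extra_chains
    if has_ion:
        names.append("NA")
        elems.append("Na")
        resnums.append(next_resnum)
        resnames.append("NA")
        chains.append("I")
    n_total = len(names)

    # --- splay bookkeeping -----------------------------------------------
    splay_moves = []
    for ev in schedule.splay:
        idx_a = _helix_atom_indices(structure, helices, ev.pair[0])
        idx_b = _helix_atom_indices(structure, helices, ev.pair[1])
        ca_a = structure.coords[idx_a][structure.atom_names[idx_a].astype(str) == "CA"]
        ca_b = structure.coords[idx_b][structure.atom_names[idx_b].astype(str) == "CA"]
        axy_a, axy_b = ca_a[:, :2].mean(axis=0), ca_b[:, :2].mean(axis=0)
        sep = axy_b - axy_a
        d0 = float(np.linalg.norm(sep))
        unit = np.array([*(sep / d0), 0.0])
        splay_moves.append((ev, idx_a, idx_b, d0, unit))

    frames = np.empty((n_frames, n_total, 3))
    for k in range(n_frames):
        coords = structure.coords.copy()
        for ev, idx_a, idx_b, d0, unit in splay_moves:
            if k <= ev.start_frame:
                target = ev.start_distance
            elif k >= ev.end_frame:
                target = ev.end_distance
            else:
                frac = (k - ev.start_frame) / (ev.end_frame - ev.start_frame)
                target = ev.start_distance + frac * (ev.end_distance - ev.start_distance)
            delta = target - d0
            coords[idx_a] -= 0.5 * delta * unit
            coords[idx_b] += 0.5 * delta * unit
        if schedule.rigid_drift:
            coords = coords + np.array([schedule.rigid_drift * k, 0.0, 0.0])
        parts = [coords]
        if water_tracks:
            waters = np.stack([t[k] for t in water_tracks])
            if schedule.rigid_drift:
                waters = waters + np.array([schedule.rigid_drift * k, 0.0, 0.0])
            parts.append(waters)
        if has_ion:
            if bound[k]:
                ion_pos = coords[site_oxy_idx].mean(axis=0)
            else:
                ion_pos = ion_park
            parts.append(ion_pos[None, :])
        frame = np.concatenate(parts, axis=0)
        if schedule.noise_sigma > 0:
            frame = frame + rng.normal(0.0, schedule.noise_sigma, frame.shape)
        frames[k] = frame

    topology = Structure(
        names, elems, resnums, resnames, chains, frames[0],
        model_id=structure.model_id,
    )
    times = np.arange(n_frames, dtype=float) * dt_ns
    return Trajectory(topology, frames, np.repeat(box[None, :], n_frames, axis=0), times)


def _smooth_profile(rng: np.random.Generator, n: int, n_modes: int = 6) -> np.ndarray:
    """Low-frequency random scalar profile along the atom index."""
    t = np.linspace(0.0, 2.0 * np.pi, n)
    out = np.zeros(n)
    for m in range(1, n_modes + 1):
        out += rng.normal() * np.sin(m * t) + rng.normal() * np.cos(m * t)
    return out


def _project_out(profile: np.ndarray, constraints: list[np.ndarray]) -> np.ndarray:
    basis, _ = np.linalg.qr(np.column_stack(constraints))
    return profile - basis @ (basis.T @ profile)


def make_model_set(
    spec: BundleSpec = BundleSpec(),
    k: int = 6,
    planted_coords: np.ndarray | None = None,
    rmsd_scale: float = 2.0,
    seed: int = 0,
) -> tuple[list[Structure], np.ndarray]:
    """Variants of the base bundle with exactly planted mutual backbone RMSDs.

    Each variant i displaces the backbone by ``x_i * u + y_i * w`` where
    (x_i, y_i) are planted 2D coordinates and u, w are unit-RMSD
    displacement fields built from smooth low-frequency amplitude profiles
    along two fixed perpendicular directions.  The profiles are projected
    orthogonal to all rigid-body modes (zero net translation and torque)
    and to each other, which keeps the cross-covariance between any two
    variants symmetric positive definite: the optimal superposition is
    then exactly the identity and the pairwise backbone RMSD equals the
    planted Euclidean distance |p_i - p_j| — hence the planted
    configuration is exactly 2D-embeddable by construction.  Smoothness
    keeps the helices locally intact, mimicking the gradual fold
    divergence between structure predictors rather than atomic noise.

    Returns the variants and the planted coordinates actually used.
    """
    if k < 2:
        raise GeometryError("need k >= 2 model variants")
    base, helices, _ = make_bundle(spec)
    rng = np.random.default_rng(seed)
    if planted_coords is None:
        planted_coords = rng.normal(0.0, rmsd_scale, size=(k, 2))
    planted_coords = np.asarray(planted_coords, dtype=float)
    if planted_coords.shape != (k, 2):
        raise GeometryError(f"planted_coords must be ({k}, 2)")

    sel_idx = resolve_selection(base, SelectionSpec(atom_class="backbone"))
    sel_coords = base.coords[sel_idx]
    rel = sel_coords - sel_coords.mean(axis=0)
    n_sel = sel_idx.size
    ones = np.ones(n_sel)
    # u displaces along x: torque-free needs sum a*r_y = sum a*r_z = 0
    profile_a = _project_out(_smooth_profile(rng, n_sel),
                             [ones, rel[:, 1], rel[:, 2]])
    # w displaces along y: torque-free needs sum b*r_x = sum b*r_z = 0;
    # orthogonality to profile_a kills the remaining cross term
    profile_b = _project_out(_smooth_profile(rng, n_sel),
                             [ones, rel[:, 0], rel[:, 2], profile_a])
    for profile in (profile_a, profile_b):
        norm = np.linalg.norm(profile)
        if norm < 1e-9:
            raise GeometryError("degenerate displacement profile; change seed")
        profile *= math.sqrt(n_sel) / norm
    u_field = np.zeros((n_sel, 3))
    u_field[:, 0] = profile_a
    w_field = np.zeros((n_sel, 3))
    w_field[:, 1] = profile_b

    # non-backbone atoms (CB, pocket oxygens) follow their residue's CA so
    # residues stay intact; the backbone RMSD is unaffected by them
    ca_disp_row = {}
    for row, atom_idx in enumerate(sel_idx):
        if base.atom_names[atom_idx] == "CA":
            ca_disp_row[int(base.residue_numbers[atom_idx])] = row
    follow = []  # (atom index, row in field arrays)
    sel_set = set(int(i) for i in sel_idx)
    for atom_idx in range(base.n_atoms):
        if atom_idx in sel_set:
            continue
        resnum = int(base.residue_numbers[atom_idx])
        if resnum in ca_disp_row:
            follow.append((atom_idx, ca_disp_row[resnum]))

    models = []
    for i in range(k):
        coords = base.coords.copy()
        disp = planted_coords[i, 0] * u_field + planted_coords[i, 1] * w_field
        coords[sel_idx] += disp
        for atom_idx, row in follow:
            coords[atom_idx] += disp[row]
        models.append(base.with_coords(coords, model_id=f"model_{i + 1}"))
    return models, planted_coords
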