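"""Structures, trajectories, Ballesteros-Weinstein maps and atom selections.

The in-memory model is deliberately small: a :class:`Structure` is a flat,
ordered atom table (names, residues, chain, Cartesian coordinates in
angstroms) and a :class:`Trajectory` is a structure plus a stack of
coordinate frames with per-frame orthorhombic box lengths and time stamps
in nanoseconds.  Residue numbering is kept exactly as in the source file
(1-based, never renumbered) so that Ballesteros-Weinstein (BW) lookups and
helix ranges stay anchored to the deposited numbering.

File formats: multi-model PDB (via biotite) is the portable baseline for
both structures and trajectories; a plain-text whitespace frame format
(``tmbundle-frames v1``) carries per-frame box and time information that
PDB cannot.  BW maps are two-column TSV; helix ranges are YAML.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigError,
    EmptyInputError,
    SelectionError,
    StructureParseError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "BWMap",
    "HelixSet",
    "SelectionSpec",
    "read_structures",
    "write_structures",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "bw_lookup",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: residue names treated as water / monoatomic ions when classifying records
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "SPC"})
ION_RESNAMES = frozenset({"NA", "SOD", "CL", "CLA", "K", "POT", "MG", "CA2"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position in angstroms."""

    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


def _element_from_name(atom_name: str) -> str:
    """Infer the element from leading alphabetic characters of an atom name.

    ``CA`` -> C (calcium would be an ion residue, handled by residue name),
    ``OD1`` -> O, ``1HB`` -> H, ``NA`` (ion) -> NA via two-letter match only
    when the full name is a known ion symbol.
    """
    stripped = atom_name.strip()
    if stripped.upper() in {"NA", "CL", "MG", "K", "ZN", "FE", "BR"}:
        return stripped.upper().capitalize()
    m = re.search(r"[A-Za-z]", stripped)
    if m is None:
        raise StructureParseError(f"cannot infer element from atom name {atom_name!r}")
    return m.group(0).upper()


class Structure:
    """An ordered atom table for one model.

    Stored column-wise (numpy arrays) for speed; :meth:`atoms` iterates
    row-wise :class:`AtomRecord` views.  The triple
    ``(chain_id, residue_number, atom_name)`` must be unique.
    """

    def __init__(
        self,
        atom_names: Sequence[str],
        elements: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        coords: np.ndarray,
        model_id: str = "model",
        hetero: Sequence[bool] | None = None,
    ) -> None:
        n = len(atom_names)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = np.array(coords, dtype=float)
        self.model_id = str(model_id)
        if hetero is None:
            hetero = [
                rn in WATER_RESNAMES or rn in ION_RESNAMES for rn in self.residue_names
            ]
        self.hetero = np.asarray(hetero, dtype=bool)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        for arr in (self.elements, self.residue_numbers, self.residue_names,
                    self.chain_ids, self.hetero):
            if len(arr) != n:
                raise ValueError("all atom columns must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain_ids, self.residue_numbers, self.atom_names))
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom key {k}")
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def __len__(self) -> int:
        return self.n_atoms

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                atom_name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                residue_number=int(self.residue_numbers[i]),
                residue_name=str(self.residue_names[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.coords[i].copy(),
            )

    def with_coords(self, coords: np.ndarray, model_id: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return Structure(
            self.atom_names, self.elements, self.residue_numbers,
            self.residue_names, self.chain_ids, coords,
            model_id=self.model_id if model_id is None else model_id,
            hetero=self.hetero,
        )

    def atom_table_equal(self, other: "Structure", coord_tol: float = 0.0) -> bool:
        if self.n_atoms != other.n_atoms:
            return False
        same_meta = (
            np.array_equal(self.atom_names, other.atom_names)
            and np.array_equal(self.elements, other.elements)
            and np.array_equal(self.residue_numbers, other.residue_numbers)
            and np.array_equal(self.residue_names, other.residue_names)
            and np.array_equal(self.chain_ids, other.chain_ids)
        )
        if not same_meta:
            return False
        if coord_tol == 0.0:
            return bool(np.array_equal(self.coords, other.coords))
        return bool(np.allclose(self.coords, other.coords, atol=coord_tol))

    def subset(self, indices: np.ndarray, model_id: str | None = None) -> "Structure":
        """New Structure containing only the atoms at *indices* (in order)."""
        idx = np.asarray(indices, dtype=int)
        return Structure(
            self.atom_names[idx], self.elements[idx], self.residue_numbers[idx],
            self.residue_names[idx], self.chain_ids[idx], self.coords[idx],
            model_id=self.model_id if model_id is None else model_id,
            hetero=self.hetero[idx],
        )

    def is_water(self) -> np.ndarray:
        return np.isin(self.residue_names.astype(str), list(WATER_RESNAMES))

    def is_ion(self) -> np.ndarray:
        return np.isin(self.residue_names.astype(str), list(ION_RESNAMES))


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    frames: (n_frames, n_atoms, 3) angstrom coordinates.
    box:    (n_frames, 3) orthorhombic box edge lengths, angstroms.
    times:  (n_frames,) strictly increasing time stamps, nanoseconds.
    """

    topology: Structure
    frames: np.ndarray
    box: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        n = self.n_frames
        if self.box.shape != (n, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.times.shape != (n,):
            raise ValueError("times must have shape (n_frames,)")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def duration_ns(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def frame_structure(self, index: int, model_id: str | None = None) -> Structure:
        if not -self.n_frames <= index < self.n_frames:
            raise IndexError(f"frame index {index} out of range")
        return self.topology.with_coords(
            self.frames[index],
            model_id=model_id or f"{self.topology.model_id}:frame{index}",
        )

    def strided(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(
            self.topology, self.frames[::stride], self.box[::stride],
            self.times[::stride],
        )


_BW_LABEL_RE = re.compile(r"^(\d+)\.(\d+)$")


class BWMap:
    """Residue number <-> Ballesteros-Weinstein label (``T.NN`` / ``45.50``)."""

    def __init__(self, entries: Mapping[int, str]) -> None:
        self._forward: dict[int, str] = {}
        self._inverse: dict[str, int] = {}
        for resnum, label in entries.items():
            resnum = int(resnum)
            label = str(label)
            if _BW_LABEL_RE.match(label) is None:
                raise ConfigError(f"BW label {label!r} does not parse as segment.index")
            if label in self._inverse:
                raise ConfigError(f"BW label {label!r} mapped to more than one residue")
            self._forward[resnum] = label
            self._inverse[label] = resnum

    @property
    def entries(self) -> dict[int, str]:
        return dict(self._forward)

    def label_of(self, residue_number: int) -> str:
        return self._forward[int(residue_number)]

    def residue_of(self, label: str) -> int:
        if label not in self._inverse:
            raise KeyError(f"BW label {label!r} not present in map")
        return self._inverse[label]

    def __contains__(self, label: str) -> bool:
        return label in self._inverse

    def __len__(self) -> int:
        return len(self._forward)

    @staticmethod
    def parse_label(label: str) -> tuple[int, int]:
        m = _BW_LABEL_RE.match(label)
        if m is None:
            raise ConfigError(f"BW label {label!r} does not parse")
        return int(m.group(1)), int(m.group(2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BWMap":
        entries: dict[int, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise StructureParseError(
                    f"{path}:{lineno}: expected two columns (residue_number, label)"
                )
            try:
                resnum = int(parts[0])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}:{lineno}: residue number {parts[0]!r} is not an integer"
                ) from exc
            entries[resnum] = parts[1]
        if not entries:
            raise EmptyInputError(f"{path}: BW map contains no entries")
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{resnum}\t{label}" for resnum, label in sorted(self._forward.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def bw_lookup(bwmap: BWMap, label: str) -> int:
    """Residue number carrying BW position *label* (e.g. ``"2.50"`` -> 69)."""
    return bwmap.residue_of(label)


class HelixSet:
    """Named inclusive residue-number intervals for the TM helices (and H8)."""

    MIN_HELIX_RESIDUES = 6

    def __init__(self, ranges: Mapping[str, tuple[int, int]]) -> None:
        self._ranges: dict[str, tuple[int, int]] = {}
        spans: list[tuple[int, int, str]] = []
        for name, (start, end) in ranges.items():
            start, end = int(start), int(end)
            if end - start + 1 < self.MIN_HELIX_RESIDUES:
                raise ConfigError(
                    f"helix {name}: interval [{start}, {end}] shorter than "
                    f"{self.MIN_HELIX_RESIDUES} residues"
                )
            spans.append((start, end, name))
            self._ranges[str(name)] = (start, end)
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError(f"helix intervals {n1} and {n2} overlap")

    @property
    def ranges(self) -> dict[str, tuple[int, int]]:
        return dict(self._ranges)

    def __contains__(self, name: str) -> bool:
        return name in self._ranges

    def names(self) -> list[str]:
        return list(self._ranges)

    def residues(self, name: str) -> range:
        if name not in self._ranges:
            raise KeyError(f"helix {name!r} not defined")
        start, end = self._ranges[name]
        return range(start, end + 1)

    def all_residues(self) -> set[int]:
        out: set[int] = set()
        for name in self._ranges:
            out.update(self.residues(name))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HelixSet":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or "helices" not in data:
            raise ConfigError(f"{path}: expected a top-level 'helices' mapping")
        return cls({k: (v[0], v[1]) for k, v in data["helices"].items()})

    def to_yaml(self, path: str | Path) -> None:
        data = {"helices": {k: [int(a), int(b)] for k, (a, b) in self._ranges.items()}}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection.

    atom_class: ``backbone`` (N, CA, C, O), ``heavy`` (element != H) or
    ``ca`` (CA only).  Optionally restricted to a helix subset and/or an
    explicit residue whitelist.  Waters and ions are never part of a
    protein selection.
    """

    atom_class: str = "backbone"
    helices: tuple[str, ...] | None = None
    residues: frozenset[int] | None = None

    _CLASSES = ("backbone", "heavy", "ca")

    def __post_init__(self) -> None:
        if self.atom_class not in self._CLASSES:
            raise ConfigError(
                f"atom_class must be one of {self._CLASSES}, got {self.atom_class!r}"
            )
        if self.helices is not None:
            object.__setattr__(self, "helices", tuple(self.helices))
        if self.residues is not None:
            object.__setattr__(self, "residues", frozenset(int(r) for r in self.residues))


def resolve_selection(
    struct: Structure,
    sel: SelectionSpec,
    helices: HelixSet | None = None,
) -> np.ndarray:
    """Resolve *sel* on *struct* to a sorted array of atom indices.

    Deterministic and order-stable: indices follow the structure's atom
    order.  Raises :class:`SelectionError` when nothing matches or when a
    requested helix subset has no HelixSet to resolve against.
    """
    mask = ~(struct.is_water() | struct.is_ion())
    if sel.atom_class == "backbone":
        mask &= np.isin(struct.atom_names.astype(str), BACKBONE_ATOMS)
    elif sel.atom_class == "ca":
        mask &= struct.atom_names.astype(str) == "CA"
    else:  # heavy
        mask &= struct.elements.astype(str) != "H"

    allowed: set[int] | None = None
    if sel.helices is not None:
        if helices is None:
            raise SelectionError("selection names helices but no HelixSet was given")
        allowed = set()
        for name in sel.helices:
            allowed.update(helices.residues(name))
    if sel.residues is not None:
        allowed = sel.residues if allowed is None else (allowed & set(sel.residues))
    if allowed is not None:
        mask &= np.isin(struct.residue_numbers, sorted(allowed))

    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {sel} resolved to zero atoms")
    return idx


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> int:
    """Validate coordinate fields of ATOM/HETATM lines, reporting line numbers.

    Returns the number of atom records found.
    """
    n_atoms = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n_atoms += 1
        if len(line) < 54:
            raise StructureParseError(f"{path}:{lineno}: truncated ATOM/HETATM record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}:{lineno}: malformed {what} coordinate "
                    f"{line[lo:hi]!r}"
                ) from exc
        try:
            int(line[22:26])
        except ValueError as exc:
            raise StructureParseError(
                f"{path}:{lineno}: malformed residue number {line[22:26]!r}"
            ) from exc
    return n_atoms


def _structure_from_atom_array(arr, model_id: str) -> Structure:
    elements = [
        el if el else _element_from_name(name)
        for el, name in zip(arr.element, arr.atom_name)
    ]
    chain_ids = [c if c.strip() else "A" for c in arr.chain_id]
    return Structure(
        atom_names=list(arr.atom_name),
        elements=[e.upper() if len(e) == 1 else e.capitalize() for e in elements],
        residue_numbers=list(arr.res_id),
        residue_names=list(arr.res_name),
        chain_ids=chain_ids,
        # PDB coordinates carry exactly 3 decimals; rounding removes the
        # float32 representation noise introduced by the reader
        coords=np.round(np.asarray(arr.coord, dtype=float), 3),
        model_id=model_id,
        hetero=list(arr.hetero),
    )


def read_structures(path: str | Path, dialect: str = "pdb_multimodel") -> list[Structure]:
    """Read one structure per MODEL record from a (multi-model) PDB file."""
    import biotite.structure.io.pdb as pdb

    if dialect != "pdb_multimodel":
        raise ConfigError(f"unknown structure dialect {dialect!r}")
    path = Path(path)
    if _prescan_pdb(path) == 0:
        raise EmptyInputError(f"{path}: no atoms found")
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite's errors carry no line context
        raise StructureParseError(f"{path}: {exc}") from exc
    stem = path.stem
    out = []
    for i in range(stack.stack_depth()):
        out.append(_structure_from_atom_array(stack[i], model_id=f"{stem}:{i + 1}"))
    return out


def _atom_array_from_structure(struct: Structure, coords: np.ndarray | None = None):
    import biotite.structure as bst

    n = struct.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(struct.coords if coords is None else coords, dtype=float)
    arr.atom_name = struct.atom_names.astype("U6")
    arr.res_id = struct.residue_numbers
    arr.res_name = struct.residue_names.astype("U5")
    arr.chain_id = struct.chain_ids.astype("U4")
    arr.element = struct.elements.astype("U2")
    arr.hetero = struct.hetero
    return arr


def write_structures(
    structures: Sequence[Structure],
    path: str | Path,
    box: np.ndarray | None = None,
) -> None:
    """Write structures as a multi-model PDB (MODEL/ENDMDL per structure)."""
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdb

    if not structures:
        raise EmptyInputError("no structures to write")
    ref = structures[0]
    arrays = []
    for s in structures:
        if s.n_atoms != ref.n_atoms:
            raise ValueError("all models must share one topology for multi-model PDB")
        arrays.append(_atom_array_from_structure(s))
    stack = bst.stack(arrays)
    if box is not None:
        b = np.asarray(box, dtype=float)
        stack.box = np.repeat(np.diag(b)[None, :, :], len(arrays), axis=0)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _orthorhombic_lengths(box_matrix: np.ndarray, context: str) -> np.ndarray:
    off = box_matrix - np.diag(np.diag(box_matrix))
    if np.max(np.abs(off)) > 1e-6:
        raise ConfigError(f"{context}: only orthorhombic boxes are supported")
    return np.diag(box_matrix).astype(float)


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

FRAMES_MAGIC = "# tmbundle-frames v1"


def write_trajectory(traj: Trajectory, path: str | Path, dialect: str = "frames") -> None:
    """Write a trajectory.

    ``frames`` dialect: the documented plain-text format — a header line,
    atom count, then per frame its index, time (ns), box lengths (angstrom)
    and one ``x y z`` line per atom, full float precision.
    ``pdb_multimodel``: one MODEL per frame (box from frame 0; times are
    not representable and are dropped).
    """
    if dialect == "pdb_multimodel":
        structs = [traj.frame_structure(i) for i in range(traj.n_frames)]
        write_structures(structs, path, box=traj.box[0])
        return
    if dialect != "frames":
        raise ConfigError(f"unknown trajectory dialect {dialect!r}")
    buf = io.StringIO()
    buf.write(FRAMES_MAGIC + "\n")
    buf.write(f"natoms {traj.n_atoms}\n")
    for k in range(traj.n_frames):
        bx, by, bz = traj.box[k]
        buf.write(f"frame {k}\ntime {traj.times[k]:.17g}\n"
                  f"box {bx:.17g} {by:.17g} {bz:.17g}\n")
        np.savetxt(buf, traj.frames[k], fmt="%.17g")
    Path(path).write_text(buf.getvalue())


def read_trajectory(
    path: str | Path,
    topology: Structure | None = None,
    dialect: str = "frames",
    dt_ns: float = 1.0,
) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    For the ``frames`` dialect a topology carrying the atom identities must
    be supplied.  For ``pdb_multimodel`` the topology is taken from the
    file itself and times are synthesized as ``k * dt_ns``.
    """
    path = Path(path)
    if dialect == "pdb_multimodel":
        import biotite.structure.io.pdb as pdb

        if _prescan_pdb(path) == 0:
            raise EmptyInputError(f"{path}: no atoms found")
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
        topo = _structure_from_atom_array(stack[0], model_id=path.stem)
        n_frames = stack.stack_depth()
        if stack.box is not None:
            box = np.stack([
                _orthorhombic_lengths(stack.box[i], str(path)) for i in range(n_frames)
            ])
        else:
            span = stack.coord.reshape(-1, 3)
            box = np.repeat(
                (span.max(axis=0) - span.min(axis=0) + 20.0)[None, :], n_frames, axis=0
            )
        times = np.arange(n_frames, dtype=float) * dt_ns
        return Trajectory(
            topo, np.round(np.asarray(stack.coord, dtype=float), 3), box, times
        )

    if dialect != "frames":
        raise ConfigError(f"unknown trajectory dialect {dialect!r}")
    if topology is None:
        raise ConfigError("'frames' dialect requires a topology structure")
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != FRAMES_MAGIC:
        raise StructureParseError(f"{path}:1: missing '{FRAMES_MAGIC}' header")
    if not lines[1].startswith("natoms "):
        raise StructureParseError(f"{path}:2: expected 'natoms N'")
    n_atoms = int(lines[1].split()[1])
    if n_atoms != topology.n_atoms:
        raise StructureParseError(
            f"{path}: file has {n_atoms} atoms, topology has {topology.n_atoms}"
        )
    frames, boxes, times = [], [], []
    i = 2
    while i < len(lines):
        if not lines[i].startswith("frame "):
            raise StructureParseError(f"{path}:{i + 1}: expected 'frame K'")
        times.append(float(lines[i + 1].split()[1]))
        boxes.append([float(v) for v in lines[i + 2].split()[1:4]])
        block = lines[i + 3 : i + 3 + n_atoms]
        frames.append(np.loadtxt(io.StringIO("\n".join(block))).reshape(n_atoms, 3))
        i += 3 + n_atoms
    return Trajectory(topology, np.stack(frames), np.asarray(boxes), np.asarray(times))
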