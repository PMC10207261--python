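"""Interhelix contact maps, interface comparison, and BW-position
conservation counting.

A contact is a residue pair (one residue per helix) whose minimum
heavy-atom distance does not exceed the cutoff (default 4.5 A).  Contact
maps are computed on single structures — typically cluster centroids — and
compared as residue sets per helix side, which is how a registry shift of
the TM6-TM7 interface between two models shows up.

Conservation counting answers questions like "what fraction of receptors
carry Asp/Glu at both 2.50 and 3.39?" on an aligned FASTA MSA whose
columns for the positions of interest are supplied as anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SelectionError
from .structure_io import BWMap, HelixSet, SelectionSpec, Structure, resolve_selection

__all__ = [
    "ContactMap",
    "InterfaceDiff",
    "interhelix_contacts",
    "compare_interfaces",
    "conservation_at_positions",
    "read_alignment_fasta",
]


@dataclass
class ContactMap:
    """Residue-pair contacts between two helices with min distances (A)."""

    pairs: dict[tuple[int, int], float]
    helix_pair: tuple[str, str]
    cutoff: float

    def residues_a(self) -> set[int]:
        return {a for a, _ in self.pairs}

    def residues_b(self) -> set[int]:
        return {b for _, b in self.pairs}

    def to_frame(self, bwmap: BWMap | None = None):
        import pandas as pd

        rows = []
        for (ra, rb), dist in sorted(self.pairs.items()):
            row = {"residue_a": ra, "residue_b": rb, "min_distance_A": dist}
            if bwmap is not None:
                row["bw_a"] = bwmap.entries.get(ra, "")
                row["bw_b"] = bwmap.entries.get(rb, "")
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class InterfaceDiff:
    """Per-helix-side partition of interface residues into shared/unique."""

    shared_a: set[int]
    only_a_in_first: set[int]
    only_a_in_second: set[int]
    shared_b: set[int]
    only_b_in_first: set[int]
    only_b_in_second: set[int]
    helix_pair: tuple[str, str]


def interhelix_contacts(
    struct: Structure,
    helices: HelixSet,
    pair: tuple[str, str] = ("TM6", "TM7"),
    cutoff: float = 4.5,
) -> ContactMap:
    """Contact map between two helices of one structure.

    A residue pair enters the map iff the minimum distance between their
    heavy atoms is <= cutoff; that minimum distance is recorded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    indices = {}
    for name in pair:
        try:
            sel = SelectionSpec(atom_class="heavy", helices=(name,))
            indices[name] = resolve_selection(struct, sel, helices)
        except SelectionError as exc:
            raise SelectionError(f"helix {name!r} resolves to no heavy atoms") from exc
    idx_a, idx_b = indices[pair[0]], indices[pair[1]]
    dists = cdist(struct.coords[idx_a], struct.coords[idx_b])
    res_a = struct.residue_numbers[idx_a]
    res_b = struct.residue_numbers[idx_b]
    pairs: dict[tuple[int, int], float] = {}
    for ra in np.unique(res_a):
        rows = res_a == ra
        for rb in np.unique(res_b):
            dmin = float(dists[np.ix_(rows, res_b == rb)].min())
            if dmin <= cutoff:
                pairs[(int(ra), int(rb))] = dmin
    return ContactMap(pairs, pair, float(cutoff))


def compare_interfaces(map_a: ContactMap, map_b: ContactMap) -> InterfaceDiff:
    """Shared / unique interface residues per helix side of two maps."""
    if map_a.helix_pair != map_b.helix_pair:
        raise ValueError(
            f"helix pairs differ: {map_a.helix_pair} vs {map_b.helix_pair}"
        )
    a1, a2 = map_a.residues_a(), map_b.residues_a()
    b1, b2 = map_a.residues_b(), map_b.residues_b()
    return InterfaceDiff(
        shared_a=a1 & a2, only_a_in_first=a1 - a2, only_a_in_second=a2 - a1,
        shared_b=b1 & b2, only_b_in_first=b1 - b2, only_b_in_second=b2 - b1,
        helix_pair=map_a.helix_pair,
    )


def read_alignment_fasta(path) -> list[tuple[str, str]]:
    """Aligned FASTA -> list of (id, sequence); all sequences equal length."""
    from Bio import AlignIO

    alignment = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in alignment]


def conservation_at_positions(
    msa: Sequence[tuple[str, str]],
    anchor_columns: Mapping[str, int],
    allowed: Mapping[str, set[str] | Sequence[str]],
) -> tuple[dict[str, float], float]:
    """Fractions of sequences carrying an allowed residue at BW-anchored
    alignment columns, plus the joint fraction satisfying all positions.

    ``anchor_columns`` maps each BW label to its 0-based alignment column;
    ``allowed`` maps the same labels to accepted one-letter residues.
    Gap characters never count as allowed.
    """
    if not msa:
        raise ValueError("MSA contains no sequences")
    length = len(msa[0][1])
    for seq_id, seq in msa:
        if len(seq) != length:
            raise ValueError(f"sequence {seq_id} has length {len(seq)} != {length}")
    per_position: dict[str, float] = {}
    satisfied = np.ones(len(msa), dtype=bool)
    for label, col in anchor_columns.items():
        if not 0 <= col < length:
            raise KeyError(
                f"anchor column {col} for position {label} outside alignment "
                f"of width {length}"
            )
        allowed_set = {r.upper() for r in allowed[label]} - {"-", "."}
        hits = np.array([seq[col] in allowed_set for _, seq in msa])
        per_position[label] = float(hits.mean())
        satisfied &= hits
    return per_position, float(satisfied.mean())
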