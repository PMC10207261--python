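import numpy as np
import pytest

from tmbundle import (
    BWMap,
    HelixSet,
    SelectionSpec,
    Structure,
    Trajectory,
    bw_lookup,
    read_structures,
    read_trajectory,
    resolve_selection,
    write_structures,
    write_trajectory,
)
from tmbundle.errors import (
    ConfigError,
    EmptyInputError,
    SelectionError,
    StructureParseError,
)

MIXED_PDB = """\
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.000  10.000  10.000  1.00  0.00           C
ATOM      3  C   ALA A   1      12.000  10.500  10.000  1.00  0.00           C
ATOM      4  O   ALA A   1      12.500  11.500  10.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.000   8.600  10.200  1.00  0.00           C
ATOM      6  N   GLY A   2      12.400   9.600  10.100  1.00  0.00           N
ATOM      7  CA  GLY A   2      13.500   9.800  10.500  1.00  0.00           C
ATOM      8  C   GLY A   2      14.500  10.200  10.100  1.00  0.00           C
ATOM      9  O   GLY A   2      15.500  10.600  10.400  1.00  0.00           O
HETATM   10  O   HOH W 101      20.000  20.000  20.000  1.00  0.00           O
HETATM   11  O   HOH W 102      25.000  25.000  25.000  1.00  0.00           O
HETATM   12 NA    NA I 201      30.000  30.000  30.000  1.00  0.00          NA
END
"""


class TestPDBReading:
    def test_multimodel_atom_counts(self, tmp_path, bundle):
        structure, _, _ = bundle
        path = tmp_path / "two_models.pdb"
        write_structures([structure, structure.with_coords(structure.coords + 1.0)], path)
        models = read_structures(path)
        assert len(models) == 2
        assert all(m.n_atoms == structure.n_atoms for m in models)

    def test_round_trip_preserves_atom_table(self, tmp_path, bundle):
        structure, _, _ = bundle
        # PDB coordinate fields carry 3 decimals; quantize before writing
        # so the round trip is an identity
        quantized = structure.with_coords(np.round(structure.coords, 3))
        path = tmp_path / "rt.pdb"
        write_structures([quantized], path)
        back = read_structures(path)[0]
        assert back.atom_table_equal(quantized)

    def test_waters_and_ions_classified(self, tmp_path):
        path = tmp_path / "mixed.pdb"
        path.write_text(MIXED_PDB)
        struct = read_structures(path)[0]
        assert struct.n_atoms == 12
        assert struct.is_water().sum() == 2
        assert struct.is_ion().sum() == 1
        # protein residues keep their identity
        assert list(struct.residue_names[:5]) == ["ALA"] * 5

    def test_malformed_atom_line_reports_line_number(self, tmp_path):
        bad = MIXED_PDB.replace("11.000  10.000  10.000", "11.000  xxxxxx  10.000")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(StructureParseError, match=r":2:"):
            read_structures(path)

    def test_zero_atoms_is_empty_input(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER  nothing\nEND\n")
        with pytest.raises(EmptyInputError):
            read_structures(path)


class TestTrajectoryIO:
    def _small_traj(self, bundle, n_frames=3):
        structure, _, _ = bundle
        rng = np.random.default_rng(0)
        frames = structure.coords[None] + rng.normal(0, 0.1, (n_frames, structure.n_atoms, 3))
        box = np.tile([100.0, 100.0, 120.0], (n_frames, 1))
        return Trajectory(structure, frames, box, np.arange(n_frames) * 2.0)

    def test_frames_dialect_round_trip_exact(self, tmp_path, bundle):
        traj = self._small_traj(bundle)
        path = tmp_path / "t.frames"
        write_trajectory(traj, path)
        back = read_trajectory(path, topology=traj.topology)
        assert np.array_equal(back.frames, traj.frames)
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.box, traj.box)

    def test_pdb_dialect_round_trip(self, tmp_path, bundle):
        traj = self._small_traj(bundle)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path, dialect="pdb_multimodel")
        back = read_trajectory(path, dialect="pdb_multimodel", dt_ns=2.0)
        assert back.n_frames == traj.n_frames
        assert np.allclose(back.frames, traj.frames, atol=1.5e-3)
        assert np.allclose(back.box, traj.box)

    def test_invariants_rejected(self, bundle):
        structure, _, _ = bundle
        frames = np.repeat(structure.coords[None], 2, axis=0)
        box = np.tile([100.0, 100.0, 120.0], (2, 1))
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(structure, frames, box, np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="positive"):
            Trajectory(structure, frames, np.zeros((2, 3)), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="atoms"):
            Trajectory(structure, frames[:, :5], box, np.array([0.0, 1.0]))


class TestSelections:
    def test_backbone_counts_four_atoms_per_residue(self, bundle):
        structure, helices, _ = bundle
        sel = SelectionSpec(atom_class="backbone", helices=("TM1",))
        idx = resolve_selection(structure, sel, helices)
        assert idx.size == 4 * 25

    def test_heavy_excludes_hydrogens(self):
        names = ["N", "CA", "C", "O", "CB", "OD1", "OD2", "CG"] + [f"H{i}" for i in range(5)]
        elems = ["N", "C", "C", "O", "C", "O", "O", "C"] + ["H"] * 5
        struct = Structure(
            names, elems, [1] * 13, ["ASP"] * 13, ["A"] * 13,
            np.arange(39, dtype=float).reshape(13, 3),
        )
        idx = resolve_selection(struct, SelectionSpec(atom_class="heavy"))
        assert idx.size == 8

    def test_tm_only_selection_excludes_loops(self, bundle):
        structure, helices, _ = bundle
        tm_sel = SelectionSpec(atom_class="heavy", helices=tuple(helices.names()))
        idx = resolve_selection(structure, tm_sel, helices)
        selected_residues = set(structure.residue_numbers[idx])
        loop_residues = (
            set(structure.residue_numbers[~structure.is_water() & ~structure.is_ion()])
            - helices.all_residues()
        )
        assert loop_residues  # the generator does create loop residues
        assert selected_residues.isdisjoint(loop_residues)

    def test_resolution_is_idempotent_and_ordered(self, bundle):
        structure, helices, _ = bundle
        sel = SelectionSpec(atom_class="heavy", helices=("TM3", "TM6"))
        first = resolve_selection(structure, sel, helices)
        second = resolve_selection(structure, sel, helices)
        assert np.array_equal(first, second)
        assert np.all(np.diff(first) > 0)

    def test_empty_selection_raises(self, bundle):
        structure, helices, _ = bundle
        sel = SelectionSpec(atom_class="ca", residues=frozenset({99999}))
        with pytest.raises(SelectionError):
            resolve_selection(structure, sel, helices)


class TestBWMap:
    @pytest.fixture()
    def or51e2_map(self):
        # excerpt of the hOR51E2 numbering around the sodium pocket
        return BWMap({69: "2.50", 110: "3.39", 96: "3.25", 178: "45.50",
                      246: "6.43", 279: "7.40"})

    @pytest.mark.parametrize("label,resnum", [("2.50", 69), ("3.39", 110)])
    def test_sodium_pocket_positions(self, or51e2_map, label, resnum):
        assert bw_lookup(or51e2_map, label) == resnum

    def test_forward_inverse_identity(self, or51e2_map):
        for resnum, label in or51e2_map.entries.items():
            assert bw_lookup(or51e2_map, label) == resnum
            assert or51e2_map.label_of(resnum) == label

    def test_unknown_label_names_it(self, or51e2_map):
        with pytest.raises(KeyError, match="1.50"):
            bw_lookup(or51e2_map, "1.50")

    def test_singleton_map(self):
        assert bw_lookup(BWMap({10: "1.50"}), "1.50") == 10

    def test_tsv_round_trip(self, tmp_path, or51e2_map):
        path = tmp_path / "bw.tsv"
        or51e2_map.to_tsv(path)
        assert BWMap.from_tsv(path).entries == or51e2_map.entries

    def test_duplicate_label_rejected(self):
        with pytest.raises(ConfigError):
            BWMap({1: "2.50", 2: "2.50"})


class TestHelixSet:
    def test_yaml_round_trip(self, tmp_path, bundle):
        _, helices, _ = bundle
        path = tmp_path / "helices.yaml"
        helices.to_yaml(path)
        assert HelixSet.from_yaml(path).ranges == helices.ranges

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            HelixSet({"TM1": (1, 20), "TM2": (15, 40)})

    def test_short_helix_rejected(self):
        with pytest.raises(ConfigError, match="shorter"):
            HelixSet({"TM1": (1, 4)})
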