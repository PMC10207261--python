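import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmbundle import (
    ActivationIndexSpec,
    BWMap,
    BundleSpec,
    EventSchedule,
    IonSiteSpec,
    SelectionSpec,
    SplayEvent,
    Structure,
    Trajectory,
    activation_index,
    helix_axis,
    ion_site_occupancy,
    make_bundle,
    make_trajectory,
    rmsd_timeseries,
    tm_pair_distance,
)
from tmbundle.errors import GeometryError, SelectionError


def constant_box(n_frames, box=(100.0, 100.0, 120.0)):
    return np.tile(box, (n_frames, 1))


class TestRMSDTimeseries:
    def test_identical_frames_give_zeros(self, bundle):
        structure, helices, _ = bundle
        frames = np.repeat(structure.coords[None], 4, axis=0)
        traj = Trajectory(structure, frames, constant_box(4), np.arange(4.0))
        sel = SelectionSpec(atom_class="heavy")
        series = rmsd_timeseries(traj, structure, sel, sel, helices)
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_linear_drift_construction(self, bundle):
        """Frame k displaces the measured (non-fit) atoms by 0.1k -> series 0.1k."""
        structure, helices, _ = bundle
        fit_sel = SelectionSpec(atom_class="backbone", helices=("TM1", "TM2"))
        tm3 = set(helices.residues("TM3"))
        measure_sel = SelectionSpec(atom_class="ca", residues=frozenset(tm3))
        from tmbundle import resolve_selection

        measure_idx = resolve_selection(structure, measure_sel, helices)
        n_frames = 8
        frames = np.repeat(structure.coords[None], n_frames, axis=0)
        for k in range(n_frames):
            frames[k, measure_idx] += np.array([0.0, 0.0, 0.1 * k])
        traj = Trajectory(structure, frames, constant_box(n_frames), np.arange(float(n_frames)))
        series = rmsd_timeseries(traj, structure, fit_sel, measure_sel, helices)
        assert np.allclose(series.values, 0.1 * np.arange(n_frames), atol=1e-6)

    def test_frame_wise_independence_under_reversal(self, bundle, rng):
        structure, helices, _ = bundle
        n_frames = 5
        frames = structure.coords[None] + rng.normal(0, 0.3, (n_frames, structure.n_atoms, 3))
        times = np.arange(float(n_frames))
        traj = Trajectory(structure, frames, constant_box(n_frames), times)
        rev = Trajectory(structure, frames[::-1].copy(), constant_box(n_frames), times)
        sel = SelectionSpec(atom_class="heavy")
        forward = rmsd_timeseries(traj, structure, sel, sel, helices)
        backward = rmsd_timeseries(rev, structure, sel, sel, helices)
        assert np.allclose(backward.values, forward.values[::-1], atol=1e-12)


class TestHelixAxis:
    @staticmethod
    def ideal_helix(n=12):
        t = np.arange(n, dtype=float)
        return np.column_stack([
            2.3 * np.cos(np.radians(100) * t),
            2.3 * np.sin(np.radians(100) * t),
            1.5 * t,
        ])

    def test_helix_along_z(self):
        axis = helix_axis(self.ideal_helix())
        assert np.allclose(np.abs(axis.direction), [0, 0, 1], atol=1e-3)
        assert axis.direction[2] > 0

    def test_rotated_helix(self):
        rot = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        axis = helix_axis(self.ideal_helix() @ rot.T)
        assert np.allclose(np.abs(axis.direction), [0, 1, 0], atol=1e-3)

    def test_points_on_line_have_zero_residual(self):
        line = np.outer(np.arange(8.0), [0.0, 0.0, 1.0]) + np.array([3.0, 4.0, 0.0])
        axis = helix_axis(line)
        resid = line - axis.point - np.outer((line - axis.point) @ axis.direction, axis.direction)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            helix_axis(self.ideal_helix(5))


class TestTMPairDistance:
    def test_parallel_helices_ten_angstroms(self, two_helix_bundle):
        structure, helices, _ = two_helix_bundle
        frames = np.repeat(structure.coords[None], 3, axis=0)
        traj = Trajectory(structure, frames, constant_box(3), np.arange(3.0))
        series = tm_pair_distance(traj, helices, pair=("TM1", "TM2"))
        assert np.allclose(series.values, 10.0, atol=0.3)

    def test_helix_against_itself_is_zero(self, two_helix_bundle):
        structure, helices, _ = two_helix_bundle
        frames = structure.coords[None]
        traj = Trajectory(structure, frames, constant_box(1), np.zeros(1))
        series = tm_pair_distance(traj, helices, pair=("TM1", "TM1"))
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_splay_schedule_recovered(self, bundle):
        structure, helices, _ = bundle
        schedule = EventSchedule(
            splay=(SplayEvent(("TM6", "TM7"), 0, 99, 8.0, 14.0),),
            noise_sigma=0.2, seed=11,
        )
        traj = make_trajectory(structure, helices, schedule, n_frames=100)
        series = tm_pair_distance(traj, helices)
        assert series.values[0] == pytest.approx(8.0, abs=0.5)
        assert series.values[-1] == pytest.approx(14.0, abs=0.5)
        # monotone up to the noise scale
        assert np.all(np.diff(series.values) > -3 * 0.2)

    def test_missing_helix_rejected(self, two_helix_bundle):
        structure, helices, _ = two_helix_bundle
        traj = Trajectory(structure, structure.coords[None], constant_box(1), np.zeros(1))
        with pytest.raises(SelectionError):
            tm_pair_distance(traj, helices, pair=("TM6", "TM7"))

    def test_frame_permutation_permutes_values(self, bundle, rng):
        structure, helices, _ = bundle
        schedule = EventSchedule(
            splay=(SplayEvent(("TM6", "TM7"), 0, 9, 8.0, 14.0),),
            noise_sigma=0.1, seed=2,
        )
        traj = make_trajectory(structure, helices, schedule, n_frames=10)
        series = tm_pair_distance(traj, helices)
        perm = rng.permutation(10)
        permuted = Trajectory(traj.topology, traj.frames[perm], traj.box,
                              traj.times)
        series_p = tm_pair_distance(permuted, helices)
        assert np.allclose(series_p.values, series.values[perm], atol=1e-12)


def planted_ca_structure(distances):
    """CA-only chain whose consecutive helix-pair distances are planted."""
    xs = np.concatenate([[0.0], np.cumsum(distances)])
    coords = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    n = len(xs)
    return Structure(["CA"] * n, ["C"] * n, range(1, n + 1), ["ALA"] * n,
                     ["A"] * n, coords), BWMap({i + 1: f"{i + 1}.50" for i in range(n)})


class TestActivationIndex:
    def test_intercept_only(self, bundle):
        structure, helices, _ = bundle
        traj = Trajectory(structure, structure.coords[None],
                          constant_box(1), np.zeros(1))
        _, _, bwmap = bundle
        spec = ActivationIndexSpec(terms=(), intercept=-1.0)
        series = activation_index(traj, bwmap, spec)
        assert np.allclose(series.values, -1.0)

    def test_single_term_reads_planted_distance(self):
        struct, bwmap = planted_ca_structure([10.0])
        traj = Trajectory(struct, struct.coords[None], constant_box(1), np.zeros(1))
        spec = ActivationIndexSpec(terms=((("1.50", "2.50"), 1.0),))
        assert activation_index(traj, bwmap, spec).values[0] == pytest.approx(10.0)

    def test_two_term_hand_value(self):
        # planted CA distances 8 and 6; value = 1.0*8 - 0.5*6 = 5
        struct, bwmap = planted_ca_structure([8.0, 6.0])
        traj = Trajectory(struct, struct.coords[None], constant_box(1), np.zeros(1))
        spec = ActivationIndexSpec(
            terms=((("1.50", "2.50"), 1.0), (("2.50", "3.50"), -0.5))
        )
        assert activation_index(traj, bwmap, spec).values[0] == pytest.approx(5.0)

    def test_linearity_in_coefficients(self):
        struct, bwmap = planted_ca_structure([8.0, 6.0, 4.0])
        traj = Trajectory(struct, struct.coords[None], constant_box(1), np.zeros(1))
        t1 = (("1.50", "2.50"), 2.0)
        t2 = (("3.50", "4.50"), -1.5)
        combined = activation_index(
            traj, bwmap, ActivationIndexSpec(terms=(t1, t2), intercept=3.0)
        )
        part1 = activation_index(traj, bwmap, ActivationIndexSpec(terms=(t1,)))
        part2 = activation_index(traj, bwmap, ActivationIndexSpec(terms=(t2,)))
        assert combined.values[0] == pytest.approx(
            3.0 + part1.values[0] + part2.values[0], abs=1e-12
        )

    def test_unresolvable_pair_named_in_error(self):
        struct, bwmap = planted_ca_structure([8.0])
        traj = Trajectory(struct, struct.coords[None], constant_box(1), np.zeros(1))
        spec = ActivationIndexSpec(terms=((("6.50", "7.50"), 1.0),))
        with pytest.raises(SelectionError, match="6.50"):
            activation_index(traj, bwmap, spec)


class TestIonSite:
    def test_ion_bound_throughout(self, bundle):
        structure, helices, bwmap = bundle
        schedule = EventSchedule(ion_binding=((0, True),), seed=0)
        traj = make_trajectory(structure, helices, schedule, n_frames=10, dt_ns=2.0)
        occupancy, first_t, _ = ion_site_occupancy(traj, bwmap)
        assert occupancy == 1.0
        assert first_t == traj.times[0]

    def test_ion_never_bound(self, bundle):
        structure, helices, bwmap = bundle
        schedule = EventSchedule(ion_binding=((0, False),), seed=0)
        traj = make_trajectory(structure, helices, schedule, n_frames=10)
        occupancy, first_t, _ = ion_site_occupancy(traj, bwmap)
        assert occupancy == 0.0
        assert first_t is None

    def test_binding_at_frame_40_of_100(self, bundle):
        structure, helices, bwmap = bundle
        schedule = EventSchedule(ion_binding=((40, True),), noise_sigma=0.2, seed=9)
        traj = make_trajectory(structure, helices, schedule, n_frames=100, dt_ns=5.0)
        occupancy, first_t, _ = ion_site_occupancy(traj, bwmap)
        assert occupancy == pytest.approx(0.60, abs=1e-12)
        assert first_t == traj.times[40]

    def test_occupancy_monotone_in_cutoff(self, bundle):
        structure, helices, bwmap = bundle
        schedule = EventSchedule(ion_binding=((0, True), (5, False), (8, True)),
                                 noise_sigma=0.3, seed=4)
        traj = make_trajectory(structure, helices, schedule, n_frames=12)
        cutoffs = [1.0, 2.0, 3.0, 5.0, 50.0]
        occ = [ion_site_occupancy(traj, bwmap, IonSiteSpec(contact_cutoff=c))[0]
               for c in cutoffs]
        assert all(0.0 <= o <= 1.0 for o in occ)
        assert all(a <= b + 1e-12 for a, b in zip(occ, occ[1:]))

    def test_missing_site_residues_rejected(self, two_helix_bundle):
        # a 2-helix bundle has no position 3.39, hence no pocket oxygens
        structure, helices, bwmap = two_helix_bundle
        traj = Trajectory(structure, structure.coords[None], constant_box(1),
                          np.zeros(1))
        with pytest.raises(SelectionError):
            ion_site_occupancy(traj, bwmap)
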