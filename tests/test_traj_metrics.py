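import numpy as np
import pytest

from cnascreen import (
    CORE_REGIONS,
    CoreRegion,
    FixtureSpec,
    LJParamTable,
    Trajectory,
    assign_secondary_structure,
    backbone_rmsd_between,
    contact_fraction,
    core_rmsd_series,
    find_sheet_hbond_pairs,
    group_indices,
    hbond_distance_series,
    infer_exclusions,
    kabsch_superpose,
    lj_energy,
    make_jitter_trajectory,
    make_two_strand_parallel,
    sheet_content,
)
from cnascreen.traj_metrics import lj_energy_series


def quaternion_rmsd(ref, mob):
    """Independent oracle: optimal-superposition RMSD via the quaternion method."""
    ref = ref - ref.mean(axis=0)
    mob = mob - mob.mean(axis=0)
    m = mob.T @ ref
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(ref ** 2) + np.sum(mob ** 2) - 2.0 * lam) / len(ref)
    return np.sqrt(max(msd, 0.0))


def brute_force_lj(coords, ga, gb, elements, params, exclusions=frozenset()):
    """Independent oracle: explicit double loop over cross pairs."""
    total = 0.0
    for i in ga:
        for j in gb:
            if frozenset((i, j)) in exclusions:
                continue
            ei, ri = params.lookup(elements[i])
            ej, rj = params.lookup(elements[j])
            eps = np.sqrt(ei * ej)
            rmin = ri + rj
            r = np.linalg.norm(coords[i] - coords[j])
            total += eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
    return total


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestKabsch:
    def test_identical_sets_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(7, 3))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ rot90.T + np.array([5.0, -2.0, 1.0])
        rot, _, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(4, 30)
            ref = rng.normal(size=(n, 3)) * 5
            mob = ref @ _random_rotation(rng).T + rng.normal(size=(n, 3)) * 0.8
            _, _, rmsd = kabsch_superpose(ref, mob)
            assert rmsd == pytest.approx(quaternion_rmsd(ref, mob), abs=1e-8)

    def test_rotation_always_proper(self, rng):
        ref = rng.normal(size=(5, 3))
        mob = -ref  # improper best fit without the determinant correction
        rot, _, _ = kabsch_superpose(ref, mob)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_too_few_or_collinear_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


class TestCoreRmsdSeries:
    def test_frozen_trajectory_all_zero(self, two_strand):
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0.0, n_frames=10, seed=1))
        s = core_rmsd_series(traj, CoreRegion("fix", 1, 8, chain="C"))
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)
        assert len(s) == 10

    def test_matches_per_frame_oracle(self, two_strand):
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0.5, n_frames=20, seed=3))
        core = CoreRegion("fix", 1, 8, chain="C")
        s = core_rmsd_series(traj, core)
        idx = group_indices(traj.topology, "C", 1, 8)
        names = [a.name for r in traj.topology.residues() for a in r.atoms]
        bb = [i for i in idx if names[i] in ("N", "CA", "C", "O")]
        for f in range(traj.n_frames):
            oracle = quaternion_rmsd(traj.frames[0][bb], traj.frames[f][bb])
            assert s.values[f] == pytest.approx(oracle, abs=1e-10)

    def test_mean_monotone_in_sigma(self, two_strand):
        means = []
        for sigma in (0.1, 0.5, 1.0):
            traj = make_jitter_trajectory(
                two_strand, FixtureSpec(sigma=sigma, n_frames=200, seed=42))
            means.append(core_rmsd_series(traj, CoreRegion("fix", 1, 8, chain="C")).mean)
        assert means[0] < means[1] < means[2]

    def test_missing_core_residues_rejected(self, two_strand):
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0, n_frames=2, seed=1))
        with pytest.raises(ValueError):
            core_rmsd_series(traj, CORE_REGIONS["4oq1"])

    def test_builtin_core_table(self):
        assert (CORE_REGIONS["4oq1"].first, CORE_REGIONS["4oq1"].last) == (183, 223)
        assert (CORE_REGIONS["3phs"].first, CORE_REGIONS["3phs"].last) == (167, 207)
        assert (CORE_REGIONS["3kptN"].first, CORE_REGIONS["3kptN"].last) == (186, 225)
        assert (CORE_REGIONS["3kptC"].first, CORE_REGIONS["3kptC"].last) == (429, 469)


class TestLJEnergy:
    def test_minimum_depth_analytic(self):
        params = LJParamTable()
        eps, rmin_half = params.lookup("C")
        coords = np.array([[0.0, 0.0, 0.0], [2 * rmin_half, 0.0, 0.0]])
        e = lj_energy(coords, [0], [1], ["C", "C"], params)
        assert e == pytest.approx(-eps, abs=1e-12)

    def test_long_range_tends_to_zero_from_below(self):
        params = LJParamTable()
        _, rmin_half = params.lookup("O")
        energies = []
        for r in (2 * rmin_half, 2 * rmin_half + 2, 2 * rmin_half + 6, 60.0):
            coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
            energies.append(lj_energy(coords, [0], [1], ["O", "O"], params))
        assert all(e < 0 for e in energies)
        assert energies[0] < energies[1] < energies[2] < energies[3]
        assert abs(energies[-1]) < 1e-6

    def test_matches_brute_force_oracle(self, rng):
        params = LJParamTable()
        elements = ["C", "N", "O", "S", "H"]
        for _ in range(20):
            n = int(rng.integers(6, 24))
            coords = rng.uniform(0, 12, size=(n, 3))
            els = [elements[i] for i in rng.integers(0, len(elements), size=n)]
            ga = list(range(0, n // 2))
            gb = list(range(n // 2, n))
            excl = {frozenset((ga[0], gb[0]))}
            mine = lj_energy(coords, ga, gb, els, params, exclusions=excl)
            oracle = brute_force_lj(coords, ga, gb, els, params, excl)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_zero_distance_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="zero"):
            lj_energy(coords, [0], [1], ["C", "C"])

    def test_overlapping_groups_rejected(self, rng):
        coords = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="overlap"):
            lj_energy(coords, [0, 1], [1, 2], ["C"] * 4)

    def test_series_frozen_is_constant_and_separated_is_zero(self, two_strand):
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0.0, n_frames=5, seed=1))
        tag_idx = group_indices(traj.topology, "T", 101, 108)
        catcher_idx = group_indices(traj.topology, "C", 1, 8)
        s = lj_energy_series(traj, tag_idx, catcher_idx)
        assert np.ptp(s.values) == pytest.approx(0.0, abs=1e-12)
        far = traj.frames.copy()
        far[:, tag_idx, :] += np.array([0.0, -50.0, 0.0])
        s_far = lj_energy_series(Trajectory(traj.topology, far), tag_idx, catcher_idx)
        assert abs(s_far.mean) < 1e-3

    def test_exclusions_from_bond_graph_split_system_empty(self, two_strand):
        tag_idx = group_indices(two_strand, "T", 101, 108)
        catcher_idx = group_indices(two_strand, "C", 1, 8)
        assert infer_exclusions(two_strand, tag_idx, catcher_idx) == set()


class TestSheetHBonds:
    def test_ladder_recovered_at_declared_distance(self, two_strand, two_strand_spec):
        pairs = find_sheet_hbond_pairs(two_strand, ("T", 101, 108), ("C", 1, 8))
        assert len(pairs) == 7
        for p in pairs:
            assert p.reference_distance == pytest.approx(
                two_strand_spec.hbond_distance, abs=0.01)

    def test_each_atom_used_once_per_direction(self, two_strand):
        pairs = find_sheet_hbond_pairs(two_strand, ("T", 101, 108), ("C", 1, 8))
        donors = [p.donor for p in pairs]
        acceptors = [p.acceptor for p in pairs]
        # donor N may appear once as donor; an O once as acceptor
        assert len(donors) == len(set(donors))
        assert len(acceptors) == len(set(acceptors))

    def test_separated_strands_give_empty_list(self, two_strand):
        moved = two_strand.copy()
        coords = moved.coords()
        tag_idx = group_indices(moved, "T", 101, 108)
        coords[tag_idx] += np.array([0.0, -10.0, 0.0])
        moved.set_coords(coords)
        assert find_sheet_hbond_pairs(moved, ("T", 101, 108), ("C", 1, 8)) == []

    def test_frozen_trajectory_mean_equals_reference_exactly(self, two_strand):
        pairs = find_sheet_hbond_pairs(two_strand, ("T", 101, 108), ("C", 1, 8))
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0.0, n_frames=8, seed=1))
        series = hbond_distance_series(traj, pairs)
        for p in pairs:
            assert series[p.label()].mean == p.reference_distance

    def test_oscillating_distance_mean(self, two_strand):
        pairs = find_sheet_hbond_pairs(two_strand, ("T", 101, 108), ("C", 1, 8))[:1]
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0.0, n_frames=4, seed=1))
        # displace the whole tag strand along -y by -0.1/+0.1 alternately
        tag_idx = group_indices(traj.topology, "T", 101, 108)
        frames = traj.frames.copy()
        for f in range(4):
            frames[f, tag_idx, 1] += 0.1 if f % 2 else -0.1
        series = hbond_distance_series(Trajectory(traj.topology, frames), pairs)
        s = series[pairs[0].label()]
        d0 = pairs[0].reference_distance
        assert s.mean == pytest.approx(d0, abs=1e-9)  # symmetric vertical oscillation
        assert set(np.round(s.values, 6)) == {round(d0 - 0.1, 6), round(d0 + 0.1, 6)}

    def test_missing_atom_rejected(self, two_strand):
        from cnascreen.traj_metrics import HBondPair
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0.0, n_frames=2, seed=1))
        ghost = HBondPair(donor=("Z", 1, ""), acceptor=("C", 1, ""), reference_distance=3.0)
        with pytest.raises(KeyError):
            hbond_distance_series(traj, [ghost])


class TestSecondaryStructure:
    def test_two_strand_fixture_inner_residues_extended(self, two_strand):
        labels = assign_secondary_structure(two_strand)
        assert all(labels[("C", i, "")] == "E" for i in range(2, 7))
        assert all(labels[("T", i, "")] == "E" for i in range(103, 108))
        assert labels[("C", 1, "")] == "C" and labels[("T", 101, "")] == "C"

    def test_isolated_strand_has_no_e(self, two_strand):
        lone = two_strand.copy()
        del lone.chains["T"]
        labels = assign_secondary_structure(lone)
        assert set(labels.values()) == {"C"}

    def test_rigid_motion_invariance(self, two_strand, rng):
        labels_before = assign_secondary_structure(two_strand)
        moved = two_strand.copy()
        moved.set_coords(two_strand.coords() @ _random_rotation(rng).T + np.array([3.0, 9.0, -4.0]))
        assert assign_secondary_structure(moved) == labels_before

    def test_tiny_chain_all_coil(self, gly_pdb_text):
        from cnascreen import read_structure
        labels = assign_secondary_structure(read_structure(gly_pdb_text))
        assert set(labels.values()) == {"C"}


class TestSheetContent:
    def test_all_extended_is_100(self):
        labels = {("C", i, ""): "E" for i in range(1, 11)}
        assert sheet_content(labels, 1, 10) == pytest.approx(100.0)

    def test_half_extended_is_50(self):
        labels = {("C", i, ""): ("E" if i <= 5 else "C") for i in range(1, 11)}
        assert sheet_content(labels, 1, 10) == pytest.approx(50.0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            sheet_content({("C", 1, ""): "E"}, 5, 10)


class TestContactsAndDomainRmsd:
    def test_frozen_bound_fixture_full_contact(self, two_strand):
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0.0, n_frames=5, seed=1))
        tag_idx = group_indices(traj.topology, "T", 101, 108)
        catcher_idx = group_indices(traj.topology, "C", 1, 8)
        assert contact_fraction(traj, tag_idx, catcher_idx) == 1.0

    def test_far_removed_tag_zero_contact(self, two_strand):
        traj = make_jitter_trajectory(two_strand, FixtureSpec(sigma=0.0, n_frames=5, seed=1))
        tag_idx = group_indices(traj.topology, "T", 101, 108)
        catcher_idx = group_indices(traj.topology, "C", 1, 8)
        frames = traj.frames.copy()
        frames[:, tag_idx, :] += np.array([0.0, -100.0, 0.0])
        assert contact_fraction(Trajectory(traj.topology, frames),
                                tag_idx, catcher_idx) == 0.0

    def test_backbone_rmsd_between_same_structure_is_zero(self, parent_4oq1):
        assert backbone_rmsd_between(parent_4oq1, parent_4oq1) == pytest.approx(0.0, abs=1e-9)

    def test_backbone_rmsd_between_jittered_copy(self, parent_4oq1, rng):
        other = parent_4oq1.copy()
        other.set_coords(parent_4oq1.coords() + rng.normal(0, 0.3, size=(parent_4oq1.n_atoms, 3)))
        r = backbone_rmsd_between(parent_4oq1, other)
        assert 0.1 < r < 1.0
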