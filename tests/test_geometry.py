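"""Loop classification, occupancies, superposition, RMSF, and gromos clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smd_unbind import (
    AtomSpec,
    LoopSchedule,
    LoopThresholds,
    Trajectory,
    adaptive_cluster_cutoff,
    classify_loop_state,
    contact_occupancy,
    generate_toy_trajectory,
    gromos_cluster,
    hbond_occupancy,
    ionic_occupancy,
    kabsch_superpose,
    least_rmsf_monomer,
    loop_distance,
    loop_populations,
    pairwise_rmsd_matrix,
    representative_structure,
    rmsf,
)


def simple_traj(coords, elements=None, names=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return Trajectory(
        coords=coords,
        atom_names=np.array(names if names is not None else [f"A{i}" for i in range(n)]),
        elements=np.array(elements if elements is not None else ["C"] * n),
        resnames=np.array(["RES"] * n),
        resids=np.arange(1, n + 1),
        chains=np.array(["A"] * n),
    )


# ---------------------------------------------------------------------------
# Loop distance and classification
# ---------------------------------------------------------------------------

class TestLoopDistance:
    def test_known_centroid_separation(self):
        frame = np.array([[0.0, 0, 0], [0.0, 0, 0], [0.8, 0, 0], [0.8, 0, 0]])
        assert loop_distance(frame, [0, 1], [2, 3]) == pytest.approx(0.8)

    def test_coincident_sets_give_zero(self):
        frame = np.zeros((4, 3))
        assert loop_distance(frame, [0, 1], [2, 3]) == 0.0

    def test_randomized_sets_match_direct_centroid_arithmetic(self):
        rng = np.random.default_rng(8)
        frame = rng.normal(size=(6, 3))
        expected = np.linalg.norm(frame[:4].mean(axis=0) - frame[4:].mean(axis=0))
        assert loop_distance(frame, [0, 1, 2, 3], [4, 5]) == pytest.approx(expected, abs=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            loop_distance(np.zeros((4, 3)), [], [0])


class TestClassifyLoopState:
    @pytest.mark.parametrize("distance,state", [
        (0.8, "closed"),
        (1.2, "open"),
        (0.9, "intermediate"),    # boundary values are intermediate
        (1.05, "intermediate"),
        (0.95, "intermediate"),
    ])
    def test_threshold_behaviour(self, distance, state):
        assert classify_loop_state(distance) == state

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_loop_state(-0.1)

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            LoopThresholds(closed_below=1.1, open_above=1.0)


class TestLoopPopulations:
    def make_scheduled(self, fractions, n_frames=100):
        n_closed = int(fractions[0] * n_frames)
        n_mid = int(fractions[1] * n_frames)
        n_open = n_frames - n_closed - n_mid
        distances = [0.7] * n_closed + [0.95] * n_mid + [1.3] * n_open
        atoms = [AtomSpec(f"C{i}", "C", "TOY", i + 1, "A", (float(i), 0, 0)) for i in range(4)]
        schedule = LoopSchedule(loop_atoms=(0, 1), anchor_atoms=(2, 3),
                                distances=tuple(distances))
        return generate_toy_trajectory(n_frames, atoms, [0.0] * 4, schedule, seed=0)

    def test_scheduled_fractions_recovered_exactly(self):
        traj = self.make_scheduled((0.50, 0.11, 0.39))
        pops = loop_populations(traj, [0, 1], [2, 3])
        assert pops == {"closed": 0.50, "intermediate": 0.11, "open": 0.39}

    def test_all_closed_schedule(self):
        traj = self.make_scheduled((1.0, 0.0, 0.0))
        pops = loop_populations(traj, [0, 1], [2, 3])
        assert pops["closed"] == 1.0 and pops["open"] == 0.0

    def test_fractions_sum_to_one(self):
        traj = self.make_scheduled((0.2, 0.5, 0.3))
        assert sum(loop_populations(traj, [0, 1], [2, 3]).values()) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Occupancies
# ---------------------------------------------------------------------------

class TestContactOccupancy:
    def test_fixed_pair_inside_and_outside_cutoff(self):
        near = simple_traj(np.tile(np.array([[[0, 0, 0], [0.3, 0, 0]]]), (5, 1, 1)))
        far = simple_traj(np.tile(np.array([[[0, 0, 0], [0.5, 0, 0]]]), (5, 1, 1)))
        assert contact_occupancy(near, [0], [1]) == 1.0
        assert contact_occupancy(far, [0], [1]) == 0.0

    def test_boundary_distance_counts_as_contact(self):
        traj = simple_traj(np.array([[[0, 0, 0], [0.4, 0, 0]]]))
        assert contact_occupancy(traj, [0], [1]) == 1.0

    def test_hydrogens_excluded(self):
        traj = simple_traj(np.array([[[0, 0, 0], [0.1, 0, 0], [1.0, 0, 0]]]),
                           elements=["C", "H", "N"])
        # only the H is close; the heavy pair is far apart
        assert contact_occupancy(traj, [0, 1], [2]) == 0.0

    def test_mixed_frames_match_exhaustive_pair_scan(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 1.0, size=(40, 8, 3))
        traj = simple_traj(coords)
        sel_a, sel_b = [0, 1, 2], [5, 6, 7]
        hits = 0
        for f in range(40):
            found = any(np.linalg.norm(coords[f, i] - coords[f, j]) <= 0.4
                        for i in sel_a for j in sel_b)
            hits += found
        assert contact_occupancy(traj, sel_a, sel_b) == pytest.approx(hits / 40)

    @given(st.floats(min_value=0.05, max_value=1.5), st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_cutoff(self, cutoff, delta):
        rng = np.random.default_rng(17)
        traj = simple_traj(rng.uniform(0, 1.2, size=(20, 6, 3)))
        occ_small = contact_occupancy(traj, [0, 1], [4, 5], cutoff)
        occ_large = contact_occupancy(traj, [0, 1], [4, 5], cutoff + delta)
        assert occ_large >= occ_small


class TestIonicOccupancy:
    def test_permanent_salt_bridge(self):
        traj = simple_traj(np.tile(np.array([[[0, 0, 0], [0.28, 0, 0]]]), (10, 1, 1)),
                           names=["NH1", "OXT"], elements=["N", "O"])
        assert ionic_occupancy(traj, [0], [1]) == 100.0

    def test_never_in_contact(self):
        traj = simple_traj(np.tile(np.array([[[0, 0, 0], [2.0, 0, 0]]]), (10, 1, 1)))
        assert ionic_occupancy(traj, [0], [1]) == 0.0

    def test_engineered_percentage_recovered(self):
        # 394 of 1000 frames in contact -> 39.4%
        coords = np.tile(np.array([[[0.0, 0, 0], [1.0, 0, 0]]]), (1000, 1, 1))
        coords[:394, 1, 0] = 0.35
        traj = simple_traj(coords)
        assert ionic_occupancy(traj, [0], [1]) == pytest.approx(39.4)


class TestHbondOccupancy:
    def linear_frame(self, da=0.28):
        # donor at origin, H on the D->A axis, acceptor at distance da
        return [[0.0, 0, 0], [0.1, 0, 0], [da, 0, 0]]

    def bent_frame(self):
        # H at 90 degrees from the D->A axis
        return [[0.0, 0, 0], [0.0, 0.1, 0], [0.28, 0, 0]]

    def test_ideal_linear_geometry_counted(self):
        traj = simple_traj([self.linear_frame()], elements=["N", "H", "O"])
        assert hbond_occupancy(traj, 0, 1, 2) == 1.0

    def test_bent_geometry_rejected_under_30_degrees(self):
        traj = simple_traj([self.bent_frame()], elements=["N", "H", "O"])
        assert hbond_occupancy(traj, 0, 1, 2) == 0.0

    def test_long_distance_rejected(self):
        traj = simple_traj([self.linear_frame(da=0.40)], elements=["N", "H", "O"])
        assert hbond_occupancy(traj, 0, 1, 2) == 0.0

    def test_engineered_70_percent_occupancy(self):
        frames = [self.linear_frame()] * 70 + [self.bent_frame()] * 30
        traj = simple_traj(frames, elements=["N", "H", "O"])
        assert hbond_occupancy(traj, 0, 1, 2) == pytest.approx(0.70)


# ---------------------------------------------------------------------------
# Superposition / RMSD / RMSF
# ---------------------------------------------------------------------------

def quaternion_rmsd(x, y):
    """Independent oracle: optimal-rotation RMSD via the quaternion method."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = (x ** 2).sum() + (y ** 2).sum()
    return float(np.sqrt(max(e0 - 2 * lam, 0.0) / x.shape[0]))


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


class TestKabsch:
    def test_identical_sets_have_zero_rmsd(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot = random_rotation(rng)
        moved = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle_on_perturbed_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.integers(4, 12)
            x = rng.normal(size=(n, 3))
            y = x + rng.normal(scale=0.1, size=(n, 3))
            _, _, rmsd = kabsch_superpose(x, y)
            assert rmsd == pytest.approx(quaternion_rmsd(x, y), abs=1e-9)

    def test_weighted_rmsd_definition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 3))
        y = x + rng.normal(scale=0.05, size=(6, 3))
        w = rng.uniform(0.5, 2.0, size=6)
        rot, trans, rmsd = kabsch_superpose(x, y, weights=w)
        fitted = x @ rot.T + trans
        expected = np.sqrt(np.sum(w * np.sum((fitted - y) ** 2, axis=1)) / w.sum())
        assert rmsd == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)


class TestRmsf:
    def test_static_trajectory_has_zero_rmsf(self, grid_atoms):
        traj = generate_toy_trajectory(10, grid_atoms, [0.0] * len(grid_atoms), seed=0)
        assert np.allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_isotropic_sd_gives_sqrt3_rmsf(self, grid_atoms):
        # alignment uses near-static anchor atoms so the probe's fluctuation
        # is measured against an externally fixed reference frame
        sd = np.full(len(grid_atoms), 1e-4)
        sd[0] = 0.05
        traj = generate_toy_trajectory(2000, grid_atoms, sd, seed=5)
        values = rmsf(traj, selection=[0], align_selection=list(range(4, 16)))
        assert values[0] == pytest.approx(0.05 * np.sqrt(3), rel=0.10)

    def test_doubling_sd_doubles_rmsf(self, grid_atoms):
        sd = np.full(len(grid_atoms), 1e-4)
        sd[0], sd[1] = 0.04, 0.08
        traj = generate_toy_trajectory(2000, grid_atoms, sd, seed=6)
        values = rmsf(traj, selection=[0, 1], align_selection=list(range(4, 16)))
        assert values[1] / values[0] == pytest.approx(2.0, rel=0.10)

    def test_invariant_under_rigid_motion_of_all_frames(self, grid_atoms):
        sd = np.full(len(grid_atoms), 0.03)
        traj = generate_toy_trajectory(50, grid_atoms, sd, seed=7)
        base = rmsf(traj)
        rng = np.random.default_rng(8)
        moved_coords = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            rot = random_rotation(rng)
            moved_coords[f] = traj.coords[f] @ rot.T + rng.normal(size=3)
        moved = Trajectory(moved_coords, traj.atom_names, traj.elements,
                           traj.resnames, traj.resids, traj.chains)
        assert np.allclose(rmsf(moved), base, atol=1e-9)

    def test_single_frame_rejected(self, grid_atoms):
        traj = generate_toy_trajectory(1, grid_atoms, [0.0] * len(grid_atoms))
        with pytest.raises(ValueError):
            rmsf(traj)


class TestPairwiseRmsd:
    def test_zero_diagonal_and_symmetry(self, grid_atoms):
        traj = generate_toy_trajectory(6, grid_atoms, [0.05] * len(grid_atoms), seed=9)
        mat = pairwise_rmsd_matrix(traj)
        assert np.allclose(np.diag(mat), 0.0)
        assert np.allclose(mat, mat.T, atol=1e-10)

    def test_identical_frames_give_zero_off_diagonal(self, grid_atoms):
        traj = generate_toy_trajectory(3, grid_atoms, [0.0] * len(grid_atoms), seed=10)
        assert np.allclose(pairwise_rmsd_matrix(traj), 0.0, atol=1e-12)

    def test_entries_match_pairwise_kabsch_oracle(self, grid_atoms):
        traj = generate_toy_trajectory(5, grid_atoms, [0.08] * len(grid_atoms), seed=11)
        mat = pairwise_rmsd_matrix(traj)
        for i in range(5):
            for j in range(i + 1, 5):
                oracle = quaternion_rmsd(traj.coords[j], traj.coords[i])
                assert mat[i, j] == pytest.approx(oracle, abs=1e-9)

    def test_triangle_inequality_on_fixture(self, grid_atoms):
        traj = generate_toy_trajectory(6, grid_atoms, [0.05] * len(grid_atoms), seed=12)
        mat = pairwise_rmsd_matrix(traj)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert mat[i, j] <= mat[i, k] + mat[k, j] + 1e-9


# ---------------------------------------------------------------------------
# gromos clustering
# ---------------------------------------------------------------------------

def brute_force_gromos(mat, cutoff):
    """Reference implementation by literal neighbour counting on index lists."""
    remaining = list(range(len(mat)))
    clusters = []
    while remaining:
        best, best_count = None, -1
        for i in remaining:
            count = sum(1 for j in remaining if mat[i][j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in remaining if mat[best][j] <= cutoff]
        clusters.append((best, sorted(members)))
        remaining = [j for j in remaining if j not in members]
    return clusters


def random_distance_matrix(rng, n):
    pts = rng.uniform(0, 1, size=(n, 2))
    return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))


class TestGromosCluster:
    def test_everything_within_cutoff_is_one_cluster(self):
        mat = np.full((5, 5), 0.01)
        np.fill_diagonal(mat, 0.0)
        result = gromos_cluster(mat, 0.1)
        assert result.sizes == [5]
        assert result.centroids == [0]

    def test_cutoff_below_all_distances_gives_singletons(self):
        mat = np.full((4, 4), 0.5)
        np.fill_diagonal(mat, 0.0)
        result = gromos_cluster(mat, 0.1)
        assert result.sizes == [1, 1, 1, 1]

    def test_two_separated_bundles_recovered(self):
        pts = np.array([0.0, 0.01, 0.02, 1.0, 1.01])
        mat = np.abs(pts[:, None] - pts[None])
        result = gromos_cluster(mat, 0.05)
        assert result.sizes == [3, 2]
        assert set(np.flatnonzero(result.assignment == 0)) == {0, 1, 2}

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            mat = random_distance_matrix(rng, n)
            cutoff = float(rng.uniform(0.05, 0.8))
            result = gromos_cluster(mat, cutoff)
            expected = brute_force_gromos(mat.tolist(), cutoff)
            assert result.centroids == [c for c, _ in expected]
            got_members = [sorted(np.flatnonzero(result.assignment == c))
                           for c in range(result.n_clusters)]
            assert [list(m) for m in got_members] == [m for _, m in expected]

    def test_sizes_non_increasing(self):
        rng = np.random.default_rng(14)
        mat = random_distance_matrix(rng, 18)
        result = gromos_cluster(mat, 0.25)
        assert all(a >= b for a, b in zip(result.sizes, result.sizes[1:]))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            gromos_cluster(np.zeros((3, 4)), 0.1)


class TestAdaptiveCutoff:
    def test_identical_frames_stop_at_first_grid_point(self):
        mat = np.zeros((6, 6))
        cutoff, result = adaptive_cluster_cutoff(mat)
        assert cutoff == 0.05
        assert result.sizes == [6]

    def test_majority_bundle_becomes_largest_cluster(self):
        # 60/40 split: tight bundle of 6 vs tight bundle of 4, far apart
        pts = np.array([0.0, 0.002, 0.004, 0.006, 0.008, 0.01, 2.0, 2.002, 2.004, 2.006])
        mat = np.abs(pts[:, None] - pts[None])
        cutoff, result = adaptive_cluster_cutoff(mat)
        assert result.sizes[0] == 6
        assert set(np.flatnonzero(result.assignment == 0)) == set(range(6))

    def test_even_split_forces_merger(self):
        pts = np.array([0.0, 0.01, 1.0, 1.01])
        mat = np.abs(pts[:, None] - pts[None])
        cutoff, result = adaptive_cluster_cutoff(mat)
        assert result.sizes[0] > 2  # strict majority requires joining the bundles
        assert cutoff >= 0.98  # the bundles are ~1 apart; the cutoff must reach across


class TestRepresentativeAndMonomer:
    def test_single_frame_is_its_own_representative(self, grid_atoms):
        traj = generate_toy_trajectory(1, grid_atoms, [0.0] * len(grid_atoms))
        assert representative_structure(traj) == 0

    def test_planted_centroid_recovered(self):
        # star topology: frame 2 is within the starting cutoff of every bundle
        # member, the other members are pairwise beyond it, and two frames are
        # strongly deformed outliers -> frame 2 alone has a strict majority
        rng = np.random.default_rng(15)
        base = rng.normal(size=(64, 3))
        frames = []
        for i in range(5):
            if i == 2:
                frames.append(base.copy())
            else:
                frames.append(base + 0.025 * rng.standard_normal((64, 3)))
        frames.append(base + 1.0 * rng.standard_normal((64, 3)))
        frames.append(base + 1.0 * rng.standard_normal((64, 3)))
        traj = simple_traj(np.array(frames))
        assert representative_structure(traj) == 2

    def test_two_identical_frames_pick_lower_index(self, grid_atoms):
        traj = generate_toy_trajectory(2, grid_atoms, [0.0] * len(grid_atoms))
        assert representative_structure(traj) == 0

    def test_least_rmsf_monomer_selection(self):
        per = {"A": [0.08, 0.08], "B": [0.05, 0.05], "C": [0.09, 0.09]}
        assert least_rmsf_monomer(per) == "B"
        assert least_rmsf_monomer({"only": [0.3]}) == "only"
        assert least_rmsf_monomer({"b": [0.1], "a": [0.1]}) == "a"
        with pytest.raises(ValueError):
            least_rmsf_monomer({})
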