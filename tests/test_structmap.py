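import numpy as np
import pytest

import biotite.structure.io.pdb as bpdb

from maturex.structmap import (
    GeometryError,
    GreedyRMSDClustering,
    Trajectory,
    greedy_cluster,
    probe_density,
    rmsd_matrix,
    superpose,
    write_map,
)
from maturex.synth import TrajectoryTruth, gen_trajectory, make_toy_protein

from oracles import greedy_cluster_oracle, probe_recount_oracle, quaternion_superpose_rmsd


def toy_trajectory(coords, box=None, probe_mask=None):
    """Wrap raw frame coordinates (F, N, 3) into a Trajectory."""
    n = coords.shape[1]
    probe_mask = np.zeros(n, bool) if probe_mask is None else probe_mask
    return Trajectory(
        coords=coords,
        atom_names=np.where(probe_mask, "C1", "CA"),
        elements=np.array(["C"] * n),
        res_ids=np.arange(1, n + 1),
        res_names=np.where(probe_mask, "PRB", "ALA"),
        box=box,
    )


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return R, rng.normal(size=3)


class TestSuperpose:
    def test_identity(self, rng):
        ref = rng.normal(size=(12, 3))
        R, t, r = superpose(ref, ref)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert R == pytest.approx(np.eye(3))
        assert t == pytest.approx(np.zeros(3), abs=1e-12)

    def test_rigid_motion_removed(self, rng):
        ref = rng.normal(size=(10, 3))
        Rm, tm = random_rigid(rng)
        mobile = ref @ Rm.T + tm
        _, _, r = superpose(ref, mobile)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_cross_shape(self):
        # unit cross vs doubled cross: optimal rotation is the identity and
        # every point sits 1 away from its target after centroid alignment
        ref = np.array([[-1, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
        _, _, r = superpose(ref, 2.0 * ref)
        assert r == pytest.approx(1.0)

    def test_no_reflection(self):
        ref = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float)
        mirrored = ref * np.array([1, 1, -1.0])
        R, _, r = superpose(ref, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert r > 0.1  # a reflection could cheat this to zero

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError, match="collinear"):
            superpose(line, line + 1.0)

    def test_agrees_with_quaternion_oracle(self, rng):
        for _ in range(20):
            ref = rng.normal(size=(8, 3))
            mob = rng.normal(size=(8, 3))
            _, _, r = superpose(ref, mob)
            assert r == pytest.approx(quaternion_superpose_rmsd(ref, mob), abs=1e-9)


class TestRmsdMatrix:
    def test_duplicate_and_rigid_frames_are_zero(self, rng):
        base = rng.normal(size=(10, 3))
        Rm, tm = random_rigid(rng)
        frames = np.stack([base, base.copy(), base @ Rm.T + tm])
        traj = toy_trajectory(frames)
        mat = rmsd_matrix(traj, selection=np.arange(10))
        assert mat == pytest.approx(np.zeros((3, 3)), abs=1e-9)

    def test_matches_pairwise_superpose_and_oracle(self, rng):
        frames = rng.normal(size=(5, 9, 3))
        traj = toy_trajectory(frames)
        mat = rmsd_matrix(traj, selection=np.arange(9))
        assert mat == pytest.approx(mat.T)
        assert np.diagonal(mat) == pytest.approx(np.zeros(5))
        for i in range(5):
            for j in range(i + 1, 5):
                _, _, r = superpose(frames[i], frames[j])
                assert mat[i, j] == pytest.approx(r)
                assert mat[i, j] == pytest.approx(
                    quaternion_superpose_rmsd(frames[i], frames[j]), abs=1e-9
                )

    def test_empty_selection_rejected(self, rng):
        traj = toy_trajectory(rng.normal(size=(3, 5, 3)))
        with pytest.raises(ValueError):
            rmsd_matrix(traj, selection=np.array([], dtype=int))

    def test_default_selection_is_backbone(self, rng):
        coords = rng.normal(size=(2, 6, 3))
        traj = Trajectory(
            coords=coords,
            atom_names=np.array(["N", "CA", "C", "O", "CB", "CG"]),
            elements=np.array(["N", "C", "C", "O", "C", "C"]),
            res_ids=np.ones(6, int),
            res_names=np.array(["ALA"] * 6),
        )
        assert traj.backbone_indices().tolist() == [0, 1, 2]


class TestGreedyCluster:
    def test_single_cluster_when_all_close(self):
        D = np.full((4, 4), 0.05)
        np.fill_diagonal(D, 0.0)
        res = greedy_cluster(D, 0.2)
        assert res.n_clusters == 1 and set(res.labels) == {0}

    def test_two_blocks(self):
        D = np.full((6, 6), 0.9)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    D[i, j] = 0.0 if i == j else 0.1
        res = greedy_cluster(D, 0.2)
        assert res.n_clusters == 2
        assert res.labels.tolist() == [0, 0, 0, 1, 1, 1]
        assert res.centers == (0, 3)  # ties break to the lowest frame index

    def test_singleton(self):
        res = greedy_cluster(np.zeros((1, 1)), 0.2)
        assert res.labels.tolist() == [0] and res.centers == (0,)

    def test_cutoff_limits(self, rng):
        D = np.abs(rng.normal(size=(10, 10)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        assert greedy_cluster(D, np.inf).n_clusters == 1
        assert greedy_cluster(D, 0.0).n_clusters == 10

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = np.nan
        with pytest.raises(ValueError):
            greedy_cluster(D, 0.2)

    def test_matches_independent_implementation(self, rng):
        for _ in range(25):
            D = np.abs(rng.normal(scale=0.3, size=(20, 20)))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            res = greedy_cluster(D, 0.2)
            labels, centers = greedy_cluster_oracle(D, 0.2)
            assert res.labels.tolist() == labels.tolist()
            assert list(res.centers) == centers
            assert res.sizes().sum() == 20
            # every member within cutoff of its center
            for i, lab in enumerate(res.labels):
                assert D[i, res.centers[lab]] <= 0.2

    def test_sklearn_estimator_wrapper(self):
        D = np.full((4, 4), 0.05)
        np.fill_diagonal(D, 0.0)
        est = GreedyRMSDClustering(cutoff=0.2).fit(D)
        assert est.n_clusters_ == 1 and est.labels_.tolist() == [0, 0, 0, 0]
        assert est.get_params() == {"cutoff": 0.2}


class TestProbeDensity:
    def test_pinned_probe_counted_once(self):
        protein = np.array([[0.0, 0, 0], [5.0, 0, 0], [0, 5.0, 0]])
        probe = np.array([[0.3, 0, 0]])
        frames = np.tile(np.vstack([protein, probe]), (10, 1, 1))
        traj = toy_trajectory(frames, probe_mask=np.array([False] * 3 + [True]))
        pm = probe_density(traj, 0.5)
        assert pm.mean_counts.tolist() == [1.0, 0.0, 0.0]
        assert pm.n_frames == 10

    def test_minimum_image_wrapping(self):
        # probe across the periodic boundary is 0.4 nm away, not 5.6
        protein = np.array([[0.1, 3.0, 3.0]])
        probe = np.array([[5.7, 3.0, 3.0]])
        frames = np.vstack([protein, probe])[None]
        traj = toy_trajectory(frames, box=np.array([6.0, 6.0, 6.0]),
                              probe_mask=np.array([False, True]))
        assert probe_density(traj, 0.5).mean_counts.tolist() == [1.0]

    def test_no_probes_rejected(self, rng):
        traj = toy_trajectory(rng.normal(size=(2, 4, 3)))
        with pytest.raises(ValueError, match="probe"):
            probe_density(traj, 0.5)

    def test_cutoff_beyond_half_box_rejected(self):
        frames = np.zeros((1, 2, 3))
        traj = toy_trajectory(frames, box=np.array([0.9, 0.9, 0.9]),
                              probe_mask=np.array([False, True]))
        with pytest.raises(ValueError, match="half"):
            probe_density(traj, 0.5)

    def test_rigid_motion_invariance(self, rng):
        truth = TrajectoryTruth(
            protein_coords=make_toy_protein(20, 1.0), n_probes=10, n_frames=5, seed=3
        )
        traj = gen_trajectory(truth)
        moved = traj.coords.copy()
        for f in range(moved.shape[0]):
            R, t = random_rigid(rng)
            moved[f] = moved[f] @ R.T + t
        traj_moved = Trajectory(
            coords=moved, atom_names=traj.atom_names, elements=traj.elements,
            res_ids=traj.res_ids, res_names=traj.res_names, box=None,
        )
        traj_fixed = Trajectory(
            coords=traj.coords, atom_names=traj.atom_names, elements=traj.elements,
            res_ids=traj.res_ids, res_names=traj.res_names, box=None,
        )
        assert probe_density(traj_moved, 0.5).mean_counts == pytest.approx(
            probe_density(traj_fixed, 0.5).mean_counts
        )

    def test_matches_recount_oracle(self):
        truth = TrajectoryTruth(
            protein_coords=make_toy_protein(15, 0.8),
            designated=(0, 5), enrichment=4.0, n_probes=12, n_frames=20, seed=9,
        )
        traj = gen_trajectory(truth)
        pm = probe_density(traj, 0.5)
        assert np.array_equal(pm.mean_counts, probe_recount_oracle(traj, 0.5))

    def test_convergence_with_frames(self):
        # Monte-Carlo: per-atom scatter of uniform counts falls as frames grow
        cvs = []
        for n_frames in (50, 500):
            truth = TrajectoryTruth(
                protein_coords=make_toy_protein(30, 1.0), n_probes=40,
                n_frames=n_frames, seed=13,
            )
            counts = probe_density(gen_trajectory(truth), 0.5).mean_counts
            cvs.append(np.std(counts) / np.mean(counts))
        assert cvs[1] < cvs[0]


class TestWriteMap:
    def make_traj(self):
        truth = TrajectoryTruth(
            protein_coords=make_toy_protein(10, 0.8), n_probes=4, n_frames=3, seed=2
        )
        return gen_trajectory(truth)

    def test_uniform_map_uniform_bfactors(self, tmp_path):
        traj = self.make_traj()
        pm = probe_density(traj, 0.5)
        uniform = type(pm)(pm.heavy_indices, np.ones_like(pm.mean_counts), 0.5, pm.n_frames)
        path = tmp_path / "map.pdb"
        write_map(traj, uniform, path)
        arr = bpdb.PDBFile.read(str(path)).get_structure(model=1, extra_fields=["b_factor"])
        assert np.all(arr.b_factor == 1.0)
        assert len(arr) == 10  # probes excluded

    def test_round_trip_scores_to_two_decimals(self, tmp_path):
        traj = self.make_traj()
        pm = probe_density(traj, 0.5)
        scores = np.round(np.linspace(0.0, 3.21, len(pm.mean_counts)), 2)
        pm2 = type(pm)(pm.heavy_indices, scores, 0.5, pm.n_frames)
        path = tmp_path / "map.pdb"
        write_map(traj, pm2, path)
        arr = bpdb.PDBFile.read(str(path)).get_structure(model=1, extra_fields=["b_factor"])
        assert np.round(arr.b_factor, 2).tolist() == scores.tolist()

    def test_enriched_atom_carries_max(self, tmp_path):
        traj = self.make_traj()
        pm = probe_density(traj, 0.5)
        scores = np.zeros_like(pm.mean_counts)
        scores[4] = 7.5
        pm2 = type(pm)(pm.heavy_indices, scores, 0.5, pm.n_frames)
        path = tmp_path / "map.pdb"
        write_map(traj, pm2, path)
        arr = bpdb.PDBFile.read(str(path)).get_structure(model=1, extra_fields=["b_factor"])
        assert int(np.argmax(arr.b_factor)) == 4
        assert arr.b_factor.max() == pytest.approx(7.5)

    def test_incomplete_map_rejected(self, tmp_path):
        traj = self.make_traj()
        pm = probe_density(traj, 0.5)
        short = type(pm)(pm.heavy_indices[:-1], pm.mean_counts[:-1], 0.5, pm.n_frames)
        with pytest.raises(ValueError, match="cover"):
            write_map(traj, short, tmp_path / "map.pdb")


def test_trajectory_pdb_round_trip(tmp_path):
    truth = TrajectoryTruth(
        protein_coords=make_toy_protein(12, 0.9), n_probes=6, n_frames=4, seed=1
    )
    traj = gen_trajectory(truth)
    path = tmp_path / "traj.pdb"
    traj.to_pdb(path)
    back = Trajectory.from_pdb(path)
    assert back.n_frames == 4 and back.n_atoms == 18
    # PDB stores angstroms to 3 decimals -> 1e-4 nm round-trip precision
    assert np.allclose(back.coords, traj.coords, atol=1.5e-4)
    assert back.box == pytest.approx(traj.box)
    assert back.is_probe.sum() == 6
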