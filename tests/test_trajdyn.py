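"""Trajectory PCA, windowing, and residue-correlation maps."""

import math

import numpy as np
import pytest

from allokit import synthgen, trajdyn
from allokit.synthgen import as_aligned, make_trajectory, random_rotation
from allokit.trajdyn import (
    Trajectory,
    align_and_window,
    ca_pca,
    delta_correlation,
    expected_frame_count,
    load_trajectory,
    pc_plane_displacement,
    residue_correlation,
)

MULTI_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   1.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.100   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.900   0.100   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.700   1.100   0.100  1.00  0.00           C
ENDMDL
MODEL        3
ATOM      1  CA  ALA A   1       0.200   0.100   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.000   0.200   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.800   1.200   0.200  1.00  0.00           C
ENDMDL
END
"""


class TestLoading:
    def test_multi_model_pdb(self, tmp_path):
        path = tmp_path / "traj.pdb"
        path.write_text(MULTI_MODEL_PDB)
        traj = load_trajectory(path, spacing_ps=20.0)
        assert traj.n_frames == 3 and traj.n_atoms == 3
        assert traj.atom_names == ["CA"] * 3
        assert traj.coords[1, 0, 0] == pytest.approx(0.1)

    def test_roster_mismatch_names_frame(self, tmp_path):
        bad = MULTI_MODEL_PDB.replace(
            "ATOM      3  CA  ALA A   3       7.800   1.200   0.200"
            "  1.00  0.00           C\nENDMDL\nEND", "ENDMDL\nEND")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(ValueError, match="frame 2"):
            load_trajectory(path)

    def test_text_matrix(self, tmp_path):
        traj, _ = make_trajectory(n_atoms=5, n_frames=20, mode_stds=(1.0,),
                                  noise_std=0.05, seed=2)
        path = tmp_path / "traj.txt"
        np.savetxt(path, traj.coords.reshape(20, -1))
        back = load_trajectory(path, spacing_ps=20.0)
        assert back.n_frames == 20 and back.n_atoms == 5
        assert np.allclose(back.coords, traj.coords, atol=1e-6)

    def test_expected_frame_count(self):
        # a 1 microsecond run saved every 20 ps
        assert expected_frame_count(1000.0, 20.0) == 50_000
        with pytest.raises(ValueError):
            expected_frame_count(-1.0, 20.0)


class TestAlignAndWindow:
    def test_window_arithmetic(self):
        n = 50_000
        n_keep = math.ceil(0.15 * n)
        assert n_keep == 7_500 and n - n_keep == 42_500
        traj, _ = make_trajectory(n_atoms=4, n_frames=200, mode_stds=(0.5,),
                                  noise_std=0.01, seed=1)
        atraj = align_and_window(traj, final_fraction=0.15)
        assert atraj.n_frames == 30 and atraj.window_start == 170

    def test_fraction_one_keeps_all(self):
        traj, _ = make_trajectory(n_atoms=4, n_frames=50, mode_stds=(0.5,),
                                  noise_std=0.01, seed=1)
        atraj = align_and_window(traj, final_fraction=1.0)
        assert atraj.n_frames == 50 and atraj.window_start == 0

    def test_alignment_removes_pure_rigid_motion(self, rng):
        base = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 1.5, 0],
                         [11.4, 1.5, 2.0], [15.2, 0.5, 3.0]])
        frames = [base]
        for _ in range(14):
            frames.append(base @ random_rotation(rng).T + rng.normal(size=3))
        traj = Trajectory(np.array(frames), list(range(1, 6)), ["CA"] * 5)
        atraj = align_and_window(traj)
        dev = np.linalg.norm(atraj.coords - atraj.coords[0], axis=2)
        assert dev.max() < 1e-6

    def test_reference_is_pre_window_frame(self):
        traj, _ = make_trajectory(n_atoms=5, n_frames=40, mode_stds=(1.0,),
                                  noise_std=0.05, seed=3)
        atraj = align_and_window(traj, reference=0, final_fraction=0.5)
        # frame 0 of the full trajectory anchors the fit even when windowed out
        assert atraj.reference_frame == 0 and atraj.window_start == 20

    def test_bad_fraction(self):
        traj, _ = make_trajectory(n_atoms=4, n_frames=20, mode_stds=(0.5,),
                                  noise_std=0.01, seed=1)
        with pytest.raises(ValueError):
            align_and_window(traj, final_fraction=0.0)


class TestPCA:
    def test_single_mode_rank_one(self):
        traj, _ = make_trajectory(n_atoms=20, n_frames=200, mode_stds=(3.0,),
                                  noise_std=0.0, seed=1)
        pca = ca_pca(as_aligned(traj), 3)
        assert pca.variance_ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_modes_analytic_ratios(self):
        traj, _ = make_trajectory(n_atoms=30, n_frames=500,
                                  mode_stds=(2.0, 1.0), noise_std=0.0,
                                  seed=13)
        pca = ca_pca(as_aligned(traj), 5)
        assert pca.variance_ratios[0] == pytest.approx(0.8, abs=1e-9)
        assert pca.variance_ratios[1] == pytest.approx(0.2, abs=1e-9)

    def test_matches_brute_force_covariance(self):
        """Variance ratios equal eigenvalue ratios of the explicitly built
        sample covariance matrix to 1e-9 (mode + isotropic noise)."""
        traj, _ = make_trajectory(n_atoms=60, n_frames=2000, mode_stds=(3.0,),
                                  noise_std=0.1, seed=13)
        atraj = as_aligned(traj)
        pca = ca_pca(atraj, 10)
        X = atraj.coords.reshape(atraj.n_frames, -1)
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / (atraj.n_frames - 1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.max(np.abs(pca.variance_ratios - eig[:10] / eig.sum())) \
            < 1e-9

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        traj, _ = make_trajectory(n_atoms=25, n_frames=400,
                                  mode_stds=(2.0, 1.0), noise_std=0.05,
                                  seed=5)
        atraj = as_aligned(traj)
        ours = ca_pca(atraj, 5)
        ref = sklearn.PCA(n_components=5).fit(
            atraj.coords.reshape(atraj.n_frames, -1))
        assert np.allclose(ours.variance_ratios, ref.explained_variance_ratio_,
                           atol=1e-9)

    def test_components_orthonormal_and_signed(self):
        traj, _ = make_trajectory(n_atoms=20, n_frames=300,
                                  mode_stds=(2.0, 1.0, 0.5), noise_std=0.05,
                                  seed=6)
        pca = ca_pca(as_aligned(traj), 6)
        G = pca.components @ pca.components.T
        assert np.allclose(G, np.eye(6), atol=1e-9)
        for comp in pca.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_pipeline_invariant_to_uniform_rigid_motion(self, rng):
        traj, _ = make_trajectory(n_atoms=15, n_frames=100, mode_stds=(1.0,),
                                  noise_std=0.05, seed=9)
        R = random_rotation(rng)
        t = rng.normal(size=3)
        moved = Trajectory(traj.coords @ R.T + t, traj.residue_ids,
                           traj.atom_names)
        r1 = ca_pca(align_and_window(traj), 4).variance_ratios
        r2 = ca_pca(align_and_window(moved), 4).variance_ratios
        assert np.allclose(r1, r2, atol=1e-9)

    def test_degenerate_trajectory_rejected(self):
        coords = np.tile(np.arange(15.0).reshape(5, 3), (20, 1, 1))
        traj = Trajectory(coords, list(range(1, 6)), ["CA"] * 5)
        with pytest.raises(ValueError, match="variance"):
            ca_pca(as_aligned(traj), 3)


class TestPCPlaneDisplacement:
    def test_stationary_projections_zero(self):
        pca = trajdyn.PCAResult(components=np.eye(2),
                                variance_ratios=np.array([0.6, 0.4]),
                                projections=np.ones((100, 2)),
                                mean=np.zeros(2))
        assert pc_plane_displacement(pca) == 0.0

    def test_linear_drift_closed_form(self):
        """Drift from (0,0) to (3,4) with 5% windows: head mean sits at 2.5%
        of the path, tail at 97.5%, so the distance is 0.95 * 5 (up to the
        discrete window-mean correction)."""
        n = 2000
        proj = np.linspace(0, 1, n)[:, None] * np.array([3.0, 4.0])
        pca = trajdyn.PCAResult(components=np.eye(2),
                                variance_ratios=np.array([1.0, 0.0]),
                                projections=proj, mean=np.zeros(2))
        got = pc_plane_displacement(pca, 0.05, 0.05)
        expected = 5.0 * (n - 100) / (n - 1)  # window means 49.5 and 1949.5
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(4.75, abs=0.01)

    def test_invariant_to_permutation_within_windows(self, rng):
        proj = rng.normal(size=(200, 2)) + np.linspace(0, 5, 200)[:, None]
        pca = trajdyn.PCAResult(components=np.eye(2),
                                variance_ratios=np.array([1.0, 0.0]),
                                projections=proj.copy(), mean=np.zeros(2))
        base = pc_plane_displacement(pca, 0.1, 0.1)
        shuffled = proj.copy()
        shuffled[:20] = shuffled[rng.permutation(20)]
        shuffled[-20:] = shuffled[180 + rng.permutation(20)]
        pca2 = trajdyn.PCAResult(components=np.eye(2),
                                 variance_ratios=np.array([1.0, 0.0]),
                                 projections=shuffled, mean=np.zeros(2))
        assert pc_plane_displacement(pca2, 0.1, 0.1) == pytest.approx(
            base, abs=1e-12)

    def test_bad_fractions(self):
        pca = trajdyn.PCAResult(components=np.eye(2),
                                variance_ratios=np.array([1.0, 0.0]),
                                projections=np.zeros((10, 2)),
                                mean=np.zeros(2))
        with pytest.raises(ValueError):
            pc_plane_displacement(pca, 0.0, 0.05)


class TestResidueCorrelation:
    def test_identical_fluctuations_all_one(self):
        rng = np.random.default_rng(3)
        wiggle = rng.normal(size=(50, 1, 3))
        coords = np.tile(np.arange(12.0).reshape(4, 3), (50, 1, 1)) + wiggle
        traj = Trajectory(coords, list(range(1, 5)), ["CA"] * 4)
        cm = residue_correlation(as_aligned(traj))
        assert np.allclose(cm.matrix, 1.0, atol=1e-9)

    def test_antiphase_groups_minus_one(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=50)
        coords = np.zeros((50, 4, 3))
        coords[:, :2, 0] = a[:, None]
        coords[:, 2:, 0] = -a[:, None]
        coords += np.arange(4)[None, :, None] * 10.0
        traj = Trajectory(coords, list(range(1, 5)), ["CA"] * 4)
        cm = residue_correlation(as_aligned(traj))
        assert cm.matrix[0, 2] == pytest.approx(-1.0, abs=1e-9)
        assert cm.matrix[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_null_independent_noise(self):
        """Off-diagonal |rho| stays small for independent isotropic noise:
        95th percentile < 0.1 at 1,000 frames across 50 seeds."""
        worst = 0.0
        for seed in range(50):
            traj, _ = make_trajectory(n_atoms=40, n_frames=1000,
                                      mode_stds=(), noise_std=0.2, seed=seed)
            m = residue_correlation(as_aligned(traj)).matrix
            off = np.abs(m[np.triu_indices(40, 1)])
            worst = max(worst, float(np.percentile(off, 95)))
        assert worst < 0.1

    def test_invariant_to_global_rotation(self, rng):
        traj, _ = make_trajectory(n_atoms=15, n_frames=200, mode_stds=(1.0,),
                                  noise_std=0.1, seed=11)
        R = random_rotation(rng)
        rotated = Trajectory(traj.coords @ R.T, traj.residue_ids,
                             traj.atom_names)
        m1 = residue_correlation(as_aligned(traj)).matrix
        m2 = residue_correlation(as_aligned(rotated)).matrix
        assert np.allclose(m1, m2, atol=1e-9)

    def test_zero_variance_residue_flagged(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(60, 4, 3))
        coords[:, 2, :] = 1.0  # frozen residue
        traj = Trajectory(coords, list(range(1, 5)), ["CA"] * 4)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            cm = residue_correlation(as_aligned(traj))
        assert np.all(np.isnan(cm.matrix[2, :]))
        assert np.all(np.isnan(cm.matrix[:, 2]))
        assert np.isfinite(cm.matrix[0, 1])

    def test_per_coordinate_variant(self):
        traj, _ = make_trajectory(n_atoms=10, n_frames=300, mode_stds=(1.0,),
                                  noise_std=0.1, seed=12)
        cm = residue_correlation(as_aligned(traj), mode="per_coordinate")
        assert cm.mode == "per_coordinate"
        assert np.allclose(np.diag(cm.matrix), 1.0, atol=1e-9)
        assert np.allclose(cm.matrix, cm.matrix.T, atol=1e-12)


class TestDeltaCorrelation:
    @staticmethod
    def _coupled_pair(rho=0.7, seed=7):
        blocks = (list(range(5, 10)), list(range(40, 45)), rho)
        mut, _ = make_trajectory(n_atoms=60, n_frames=2000, noise_std=0.3,
                                 coupled_blocks=blocks, seed=seed)
        wt, _ = make_trajectory(n_atoms=60, n_frames=2000, noise_std=0.3,
                                seed=seed)
        return (residue_correlation(as_aligned(mut)),
                residue_correlation(as_aligned(wt)))

    def test_identical_systems_zero(self):
        traj, _ = make_trajectory(n_atoms=20, n_frames=200, mode_stds=(1.0,),
                                  noise_std=0.1, seed=2)
        cm = residue_correlation(as_aligned(traj))
        dc = delta_correlation(cm, cm, threshold=0.5)
        assert np.allclose(dc.delta, 0.0)
        assert not dc.top_positive and not dc.top_negative

    def test_injected_coupling_ranked_first(self):
        """An extra shared mode confined to two residue blocks (analytic
        block correlation 0.7) dominates the ranking and clears the 0.5
        visualization threshold."""
        target, ref = self._coupled_pair(rho=0.7, seed=7)
        dc = delta_correlation(target, ref, threshold=0.5, top_k=10)
        block = set(range(6, 11)) | set(range(41, 46))  # 1-based residues
        assert dc.top_positive[0][2] > 0.5
        for i, j, _ in dc.top_positive:
            assert i in block and j in block
        cross = [(i, j, v) for i, j, v in dc.top_positive
                 if (i < 11) != (j < 11)]
        assert cross and all(v > 0.5 for _, _, v in cross)
        assert abs(dc.top_positive[0][2] - 0.7) < 0.15

    def test_swap_antisymmetry(self):
        target, ref = self._coupled_pair(seed=8)
        fwd = delta_correlation(target, ref, threshold=0.5, top_k=5)
        rev = delta_correlation(ref, target, threshold=0.5, top_k=5)
        assert np.allclose(fwd.delta, -rev.delta, equal_nan=True)
        assert [(i, j, pytest.approx(-v)) for i, j, v in fwd.top_positive] \
            == rev.top_negative

    def test_threshold_zero_is_raw(self):
        target, ref = self._coupled_pair(seed=9)
        dc = delta_correlation(target, ref, threshold=0.0)
        assert np.allclose(dc.thresholded, dc.delta, equal_nan=True)

    def test_indexing_mismatch_lists_difference(self):
        traj, _ = make_trajectory(n_atoms=10, n_frames=50, mode_stds=(1.0,),
                                  noise_std=0.1, seed=1)
        small, _ = make_trajectory(n_atoms=9, n_frames=50, mode_stds=(1.0,),
                                   noise_std=0.1, seed=1)
        c1 = residue_correlation(as_aligned(traj))
        c2 = residue_correlation(as_aligned(small))
        with pytest.raises(ValueError, match="10"):
            delta_correlation(c1, c2)
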