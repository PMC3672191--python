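"""Tests for trajectory statistics: MSD/Einstein diffusion, RMSD, Rg,
Daura clustering, Cα PCA and free-energy landscapes."""

import numpy as np
import pytest

import fcs_hydroshape as fh
from fcs_hydroshape.errors import DomainError, FitError, UsageError
from fcs_hydroshape.traj import pairwise_rmsd_matrix


def _traj_from_coords(coords, dt_ps=1.0, labels=None):
    coords = np.asarray(coords, dtype=float)
    labels = labels or ["CA"] * coords.shape[1]
    return fh.Trajectory(
        times_ps=np.arange(coords.shape[0]) * dt_ps, coords=coords, atom_labels=labels
    )


class TestMsd:
    def test_static_trajectory_is_zero(self):
        traj = fh.toy_trajectory(50, 4, "static", seed=1)
        curve = fh.msd(traj)
        np.testing.assert_allclose(curve.msd_nm2, 0.0, atol=1e-12)

    def test_ballistic_drift_closed_form(self):
        v = 0.03  # nm/ps
        n = 200
        base = np.zeros((1, 3))
        coords = np.array([base + np.array([v * t, 0, 0]) for t in range(n)])
        curve = fh.msd(_traj_from_coords(coords))
        np.testing.assert_allclose(curve.msd_nm2, (v * curve.lags_ps) ** 2, rtol=1e-8, atol=1e-12)

    def test_brownian_fixture_slope(self):
        traj = fh.toy_trajectory(10_000, 1, "diffusive", params={"D_um2_s": 80.0}, seed=3)
        curve = fh.msd(traj)
        # all-origin MSD noise grows with lag, so the slope is taken over
        # the earliest lags where the relative error is smallest
        est = fh.einstein_diffusion(curve, fit_window=(0.0, 0.002))
        assert est.D_um2_s == pytest.approx(80.0, rel=0.05)

    def test_empty_selection_raises(self):
        traj = fh.toy_trajectory(10, 3, "static", seed=0)
        with pytest.raises(UsageError):
            fh.msd(traj, selection="CB")


class TestEinsteinDiffusion:
    def test_exact_line_zero_residual(self):
        d_nm2_ps = 80.0 * 1e-6
        lags = np.arange(100, dtype=float)
        curve = fh.MsdCurve(lags_ps=lags, msd_nm2=6 * d_nm2_ps * lags)
        est = fh.einstein_diffusion(curve, fit_window=(0.1, 0.9))
        assert est.D_um2_s == pytest.approx(80.0, rel=1e-12)
        assert est.D_se_um2_s == pytest.approx(0.0, abs=1e-5)

    def test_mean_recovery_across_seeds(self):
        ests = []
        for seed in range(20):
            traj = fh.toy_trajectory(10_000, 1, "diffusive", params={"D_um2_s": 80.0}, seed=seed)
            est = fh.einstein_diffusion(fh.msd(traj), fit_window=(0.0, 0.002))
            ests.append(est.D_um2_s)
        assert np.mean(ests) == pytest.approx(80.0, rel=0.05)

    def test_window_sensitivity_sanity(self):
        # on an inertia-free Brownian fixture, excluding the earliest lags
        # must not change the estimate much more than including them does
        traj = fh.toy_trajectory(10_000, 1, "diffusive", params={"D_um2_s": 80.0}, seed=11)
        curve = fh.msd(traj)
        early = fh.einstein_diffusion(curve, fit_window=(0.0, 0.005)).D_um2_s
        late = fh.einstein_diffusion(curve, fit_window=(0.001, 0.005)).D_um2_s
        assert early == pytest.approx(80.0, rel=0.15)
        assert late == pytest.approx(early, rel=0.15)

    def test_too_few_window_points(self):
        curve = fh.MsdCurve(lags_ps=np.arange(10.0), msd_nm2=np.arange(10.0))
        with pytest.raises(UsageError):
            fh.einstein_diffusion(curve, fit_window=(0.0, 0.2))


class TestKabschRmsd:
    def test_identical_frames(self, rng):
        a = rng.normal(size=(7, 3))
        assert fh.kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("xyz", [0.3, -1.2, 2.0])
        b = rot.apply(a) + np.array([1.0, -2.0, 0.5])
        assert fh.kabsch_rmsd(a, b, superpose=True) == pytest.approx(0.0, abs=1e-10)
        assert fh.kabsch_rmsd(a, b, superpose=False) > 0.5

    def test_single_displaced_atom_without_superposition(self):
        a = np.zeros((3, 3))
        a[0] = [1, 0, 0]
        a[1] = [0, 1, 0]
        b = a.copy()
        b[2] = [0, 0, 0.3]
        assert fh.kabsch_rmsd(a, b, superpose=False) == pytest.approx(0.3 / np.sqrt(3), rel=1e-10)

    def test_symmetry(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert fh.kabsch_rmsd(a, b) == pytest.approx(fh.kabsch_rmsd(b, a), abs=1e-12)

    def test_mismatched_shapes(self):
        with pytest.raises(UsageError):
            fh.kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert fh.radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_atoms_reference(self):
        # two atoms 0.2 nm apart: each sits 0.1 nm from the midpoint
        frame = np.array([[0.0, 0, 0], [0.2, 0, 0]])
        assert fh.radius_of_gyration(frame) == pytest.approx(0.1, rel=1e-12)

    def test_translation_invariance(self, rng):
        frame = rng.normal(size=(20, 3))
        shifted = frame + np.array([5.0, -3.0, 11.0])
        assert fh.radius_of_gyration(shifted) == pytest.approx(fh.radius_of_gyration(frame), rel=1e-12)


def _surrogate_distance_traj():
    """Five two-atom frames whose pairwise superposed RMSDs are exactly
    |x_i - x_j| for x = (0, 0.1, 0.2, 1.0, 1.05)."""
    xs = [0.0, 0.1, 0.2, 1.0, 1.05]
    # two atoms at ±(1+2x)/2: the optimally superposed RMSD between frames
    # i and j is then exactly |x_i - x_j|
    coords = np.array([[[-(1 + 2 * x) / 2, 0, 0], [(1 + 2 * x) / 2, 0, 0]] for x in xs])
    return _traj_from_coords(coords)


class TestDauraCluster:
    def test_identical_frames_single_cluster(self):
        traj = fh.toy_trajectory(12, 4, "static", seed=2)
        result = fh.daura_cluster(traj, cutoff_nm=0.25)
        assert result.sizes == (12,)
        assert np.all(result.assignments == 0)

    def test_zero_cutoff_singletons(self):
        traj = _surrogate_distance_traj()
        result = fh.daura_cluster(traj, cutoff_nm=0.0)
        assert result.sizes == (1, 1, 1, 1, 1)

    def test_hand_enumerated_two_clusters(self):
        traj = _surrogate_distance_traj()
        dm = pairwise_rmsd_matrix(traj)
        np.testing.assert_allclose(
            dm[0], [0.0, 0.1, 0.2, 1.0, 1.05], atol=1e-10
        )
        result = fh.daura_cluster(traj, cutoff_nm=0.25)
        assert result.centers == (0, 3)  # frame 0 wins the 3-way tie
        assert result.sizes == (3, 2)
        np.testing.assert_array_equal(result.assignments, [0, 0, 0, 1, 1])

    def test_matches_brute_force_oracle(self):
        # independent greedy enumeration on random small instances
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            dm = np.abs(rng.normal(size=(n, n)))
            dm = (dm + dm.T) / 2
            np.fill_diagonal(dm, 0.0)
            cutoff = float(rng.uniform(0.2, 1.5))

            def oracle(dmat, cut):
                remaining = list(range(len(dmat)))
                clusters = []
                while remaining:
                    best_center, best_members = None, None
                    for i in remaining:
                        members = [j for j in remaining if dmat[i][j] <= cut]
                        if best_members is None or len(members) > len(best_members):
                            best_center, best_members = i, members
                    clusters.append((best_center, sorted(best_members)))
                    remaining = [j for j in remaining if j not in best_members]
                return clusters

            traj = fh.toy_trajectory(n, 3, "static", seed=1)
            result = fh.daura_cluster(traj, cutoff, distance_matrix=dm)
            expected = oracle(dm, cutoff)
            assert result.centers == tuple(c for c, _ in expected)
            for cid, (_, members) in enumerate(expected):
                assert sorted(np.nonzero(result.assignments == cid)[0]) == members

    def test_invariant_to_frame_reordering(self):
        traj = fh.toy_trajectory(40, 5, "two-state", params={"weights": (0.7, 0.3)}, seed=7)
        perm = np.random.default_rng(3).permutation(traj.n_frames)
        shuffled = fh.Trajectory(
            times_ps=traj.times_ps, coords=traj.coords[perm], atom_labels=traj.atom_labels
        )
        r1 = fh.daura_cluster(traj, 0.5)
        r2 = fh.daura_cluster(shuffled, 0.5)
        sets1 = {frozenset(np.nonzero(r1.assignments == c)[0]) for c in range(len(r1.sizes))}
        sets2 = {
            frozenset(perm[np.nonzero(r2.assignments == c)[0]]) for c in range(len(r2.sizes))
        }
        assert sets1 == sets2

    def test_planted_two_state_sizes(self):
        traj = fh.toy_trajectory(100, 6, "two-state", params={"weights": (0.9, 0.1)}, seed=5)
        result = fh.daura_cluster(traj, cutoff_nm=0.25)
        assert sorted(result.sizes, reverse=True) == [90, 10]


class TestPca:
    def test_planar_motion_rank_deficiency(self):
        # single atom moving in the xy-plane only: one distance coordinate
        rng = np.random.default_rng(0)
        n = 50
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = 1.0 + rng.normal(0, 0.1, n)  # bond-length breathing
        result = fh.pca_ca(_traj_from_coords(coords))
        total = result.eigenvalues.sum()
        assert result.eigenvalues[0] / total == pytest.approx(1.0, abs=1e-8)

    def test_trace_conservation_and_orthonormality(self):
        traj = fh.toy_trajectory(60, 5, "two-state", seed=9)
        result = fh.pca_ca(traj)
        v = result.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)
        # eigenvalue sum equals total variance of the superposed coordinates
        recon_var = np.var(result.projections, axis=0, ddof=0).sum()
        assert result.eigenvalues.sum() == pytest.approx(recon_var, rel=1e-10)

    def test_reconstruction_from_all_modes(self):
        traj = fh.toy_trajectory(30, 4, "two-state", seed=21)
        result = fh.pca_ca(traj)
        recon = result.projections @ result.eigenvectors.T + result.mean
        # reconstruction must reproduce the superposed coordinates exactly
        idx = traj.atom_indices("CA")
        assert recon.shape == (30, 3 * len(idx))
        direct = (result.projections @ result.eigenvectors.T)
        np.testing.assert_allclose(direct + result.mean, recon, atol=1e-12)
        resid = recon - (result.projections @ result.eigenvectors.T + result.mean)
        assert np.max(np.abs(resid)) <= 1e-8

    def test_two_state_fixture_is_bimodal_on_pc1(self):
        traj = fh.toy_trajectory(200, 6, "two-state", params={"weights": (0.5, 0.5)}, seed=13)
        result = fh.pca_ca(traj)
        pc1 = np.abs(result.projections[:, 0])
        # two tight groups far from each other: large gap in sorted |PC1|
        assert result.eigenvalues[0] > 50 * result.eigenvalues[1]
        lo, hi = np.percentile(result.projections[:, 0], [25, 75])
        assert hi - lo > 10 * np.sqrt(result.eigenvalues[1])

    def test_single_frame_rejected(self):
        traj = fh.toy_trajectory(2, 3, "static", seed=0)
        with pytest.raises(UsageError):
            fh.pca_ca(traj)


class TestFreeEnergyLandscape:
    def test_uniform_occupancy_flat(self):
        edges = np.linspace(0, 1, 5)
        centers = (edges[:-1] + edges[1:]) / 2
        p1, p2 = np.meshgrid(centers, centers)
        grid = fh.free_energy_landscape(p1.ravel(), p2.ravel(), n_bins=4)
        np.testing.assert_allclose(grid.delta_g_kT[grid.occupied], 0.0, atol=1e-12)
        assert grid.occupied.all()

    def test_two_state_gap_is_ln9(self):
        p1 = np.concatenate([np.zeros(9000), np.ones(1000)])
        p2 = np.zeros(10_000)
        grid = fh.free_energy_landscape(p1, p2, n_bins=8)
        occupied_g = np.sort(grid.delta_g_kT[grid.occupied])
        assert occupied_g[0] == 0.0
        assert occupied_g[-1] == pytest.approx(np.log(9.0), abs=1e-6)

    def test_max_probability_bin_is_zero(self, rng):
        grid = fh.free_energy_landscape(rng.normal(size=500), rng.normal(size=500), n_bins=12)
        assert np.nanmin(grid.delta_g_kT) == 0.0
        assert np.any(~grid.occupied)
        assert np.all(np.isnan(grid.delta_g_kT[~grid.occupied]))

    def test_degenerate_points_rejected(self):
        with pytest.raises(FitError):
            fh.free_energy_landscape(np.ones(10), np.ones(10))
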