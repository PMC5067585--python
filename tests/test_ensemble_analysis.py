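import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ifaceprof.ensemble_analysis import (
    DegenerateSelectionError,
    backbone_indices,
    convergence_report,
    cosine_content,
    covariance_modes,
    gromos_cluster,
    kabsch_superpose,
    pairwise_rmsd,
    representative_structure,
    rmsd_series,
)
from ifaceprof.structure_io import Ensemble
from ifaceprof.synthetic import generate_cluster_fixture, generate_projection_series

from oracles import oracle_min_rmsd


def _rigid(x, angle_deg=90.0, axis="z", shift=(1.0, -2.0, 0.5)):
    R = Rotation.from_euler(axis, angle_deg, degrees=True).as_matrix()
    return x @ R.T + np.asarray(shift)


class TestKabsch:
    def test_identical_frames(self):
        x = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed(self):
        x = np.random.default_rng(1).normal(size=(7, 3))
        _, _, rmsd = kabsch_superpose(x, _rigid(x))
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 5, 3))
        R, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_numeric_minimization_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 5, 3))
        _, _, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(oracle_min_rmsd(x, y), abs=1e-6)

    def test_matches_mdanalysis_cross_check(self):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 9, 3))
        _, _, ours = kabsch_superpose(x, y)
        assert ours == pytest.approx(mda_rmsd(y, x, superposition=True), abs=1e-9)

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(DegenerateSelectionError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateSelectionError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_identical_frames_all_zero(self):
        ens = generate_cluster_fixture(5, 0, wobble=0.0, seed=0)
        series = rmsd_series(ens)
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_pure_translation_is_zero(self):
        base = generate_cluster_fixture(1, 0, wobble=0.0, seed=1)
        coords = np.array([base.coords[0] + np.array([0.1, 0.2, 0.0]) * i for i in range(4)])
        ens = Ensemble(base.topology, coords)
        np.testing.assert_allclose(rmsd_series(ens), 0.0, atol=1e-12)

    def test_monotone_with_designed_magnitude(self):
        base = generate_cluster_fixture(1, 0, wobble=0.0, seed=2)
        x0 = base.coords[0]
        rng = np.random.default_rng(3)
        disp = rng.normal(size=x0.shape)
        coords = np.array([x0 + disp * (0.05 * i) for i in range(5)])
        ens = Ensemble(base.topology, coords)
        series = rmsd_series(ens, selection=list(range(ens.n_atoms)))
        assert (np.diff(series) > 0).all()


class TestGromosCluster:
    def test_all_identical_frames(self):
        ens = generate_cluster_fixture(8, 0, wobble=0.0, seed=0)
        res = gromos_cluster(ens, cutoff=0.2)
        assert res.sizes == (8,)
        assert res.centroids == (0,)
        assert res.coverage == 1.0
        assert representative_structure(res) == (0, 1.0)

    def test_two_conformer_fixture(self):
        ens = generate_cluster_fixture(30, 20, separation=1.0, wobble=0.02, seed=1)
        res = gromos_cluster(ens, cutoff=0.2)
        assert res.sizes == (30, 20)
        assert res.coverage == pytest.approx(0.6)
        rep, cov = representative_structure(res)
        assert rep < 30  # centroid of the larger (first) conformer group
        assert cov > 0.5

    def test_cutoff_larger_than_spread_gives_single_cluster(self):
        ens = generate_cluster_fixture(10, 10, separation=1.0, wobble=0.02, seed=2)
        res = gromos_cluster(ens, cutoff=5.0)
        assert res.n_clusters == 1
        assert res.coverage == 1.0

    def test_equal_clusters_tie_break_to_lower_index(self):
        ens = generate_cluster_fixture(10, 10, separation=1.0, wobble=0.02, seed=3)
        res = gromos_cluster(ens, cutoff=0.2)
        assert res.sizes == (10, 10)
        assert res.centroids[0] < 10
        rep, _ = representative_structure(res)
        assert rep == res.centroids[0]

    def test_sizes_sum_to_frame_count_and_membership_consistent(self):
        ens = generate_cluster_fixture(12, 7, separation=1.0, wobble=0.02, seed=4)
        res = gromos_cluster(ens, cutoff=0.2)
        assert sum(res.sizes) == ens.n_frames
        for cid, centroid in enumerate(res.centroids):
            assert res.membership[centroid] == cid

    def test_frame_permutation_preserves_sizes(self):
        ens = generate_cluster_fixture(9, 5, separation=1.0, wobble=0.02, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ens.n_frames)
        permuted = Ensemble(ens.topology, ens.coords[perm])
        a = gromos_cluster(ens, cutoff=0.2)
        b = gromos_cluster(permuted, cutoff=0.2)
        assert a.sizes == b.sizes

    def test_global_rigid_motion_invariance(self):
        ens = generate_cluster_fixture(6, 4, separation=1.0, wobble=0.02, seed=6)
        moved = Ensemble(ens.topology, np.array([_rigid(f) for f in ens.coords]))
        np.testing.assert_allclose(
            pairwise_rmsd(ens), pairwise_rmsd(moved), atol=1e-9
        )


class TestCovariance:
    def test_identical_frames_zero_spectrum(self):
        ens = generate_cluster_fixture(6, 0, wobble=0.0, seed=0)
        res = covariance_modes(ens, n_modes=3)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-20)

    def test_single_oscillating_atom_is_rank_one(self):
        base = generate_cluster_fixture(1, 0, wobble=0.0, seed=1)
        x0 = base.coords[0]
        frames = []
        for i in range(20):
            x = x0.copy()
            x[0, 0] += 0.1 * np.sin(2 * np.pi * i / 20)
            frames.append(x)
        ens = Ensemble(base.topology, np.array(frames))
        res = covariance_modes(
            ens, selection=list(range(ens.n_atoms)), n_modes=3, superpose=False
        )
        assert res.eigenvalues[0] > 1e-5
        np.testing.assert_allclose(res.eigenvalues[1:], 0.0, atol=1e-12)
        mode = res.eigenvectors[:, 0].reshape(-1, 3)
        np.testing.assert_allclose(np.abs(mode[0]), [1.0, 0.0, 0.0], atol=1e-9)

    def test_planar_gaussian_recovers_known_spectrum(self):
        rng = np.random.default_rng(7)
        base = generate_cluster_fixture(1, 0, wobble=0.0, seed=2)
        x0 = base.coords[0]
        sx, sy = 0.3, 0.1
        n = 4000
        frames = np.repeat(x0[None], n, axis=0)
        frames[:, 0, 0] += rng.normal(0, sx, n)
        frames[:, 0, 1] += rng.normal(0, sy, n)
        ens = Ensemble(base.topology, frames)
        res = covariance_modes(
            ens, selection=list(range(ens.n_atoms)), n_modes=2, superpose=False
        )
        assert res.eigenvalues[0] == pytest.approx(sx**2, rel=0.1)
        assert res.eigenvalues[1] == pytest.approx(sy**2, rel=0.1)

    def test_eigenvalue_sum_equals_total_variance(self):
        ens = generate_cluster_fixture(10, 10, separation=1.0, wobble=0.05, seed=3)
        res = covariance_modes(ens, n_modes=2)
        total = np.mean(np.sum((res.fitted - res.fitted.mean(axis=0)) ** 2, axis=(1, 2)))
        assert res.eigenvalues.sum() == pytest.approx(total, abs=1e-9)

    def test_too_many_modes_rejected(self):
        ens = generate_cluster_fixture(4, 0, wobble=0.0, seed=4)
        with pytest.raises(ValueError):
            covariance_modes(ens, n_modes=10**6)


class TestCosineContent:
    def test_pure_half_cosine_is_one(self):
        p = generate_projection_series("cosine", 1000, mode=1)
        assert cosine_content(p, 1) == pytest.approx(1.0, abs=1e-3)

    def test_constant_series_is_zero(self):
        p = generate_projection_series("constant", 100)
        assert cosine_content(p, 1) == pytest.approx(0.0, abs=1e-12)

    def test_mode_orthogonality(self):
        p = generate_projection_series("cosine", 1000, mode=2)
        assert cosine_content(p, 2) == pytest.approx(1.0, abs=1e-3)
        assert cosine_content(p, 1) == pytest.approx(0.0, abs=1e-3)

    def test_bounded_in_unit_interval_for_random_series(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.normal(size=rng.integers(10, 300))
            c = cosine_content(p, int(rng.integers(1, 4)))
            assert 0.0 <= c <= 1.0 + 1e-12

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            cosine_content(np.zeros(10), 1)


class TestConvergenceReport:
    def test_diffusive_ensemble_flags_high_cosine_content(self):
        # an ensemble whose only motion IS a half-cosine along x
        base = generate_cluster_fixture(1, 0, wobble=0.0, seed=8)
        x0 = base.coords[0]
        n = 200
        t = np.arange(n)
        frames = np.repeat(x0[None], n, axis=0)
        frames[:, 0, 0] += 0.5 * np.cos(np.pi * t / (n - 1))
        ens = Ensemble(base.topology, frames)
        rep = convergence_report(ens, selection=list(range(ens.n_atoms)), n_modes=1)
        assert rep.cosine_contents[0] == pytest.approx(1.0, abs=0.05)

    def test_identical_frames_report_zeros(self):
        ens = generate_cluster_fixture(5, 0, wobble=0.0, seed=9)
        rep = convergence_report(ens, n_modes=2)
        np.testing.assert_allclose(rep.rmsd, 0.0, atol=1e-12)
        np.testing.assert_allclose(rep.eigenvalues, 0.0, atol=1e-20)
        assert rep.cosine_contents == (0.0, 0.0)
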