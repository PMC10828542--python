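import numpy as np
import pytest
from scipy.spatial import ConvexHull

import splitperox as sp
from splitperox.essential_dynamics import (
    gromos_cluster,
    joint_pca,
    pairwise_rmsd_matrix,
    pca,
    project_onto,
    shared_calpha_selections,
)


def noise_traj(n_res, n_frames, sigma, seed):
    helix = sp.make_helix(n_res)
    traj, _ = sp.make_trajectory(helix, sp.SyntheticSpec(n_frames=n_frames, sigma=sigma, seed=seed))
    return traj


class TestPCA:
    def test_single_oscillating_atom_dominates(self, helix20):
        frames = np.repeat(helix20.coords[None], 50, axis=0)
        ca = sp.select_calpha(helix20).indices
        frames[:, ca[0], 0] += np.sin(np.linspace(0, 6 * np.pi, 50))
        result = pca(sp.Trajectory(atom_table=helix20, frames=frames))
        assert result.explained_fraction[0] > 0.999

    def test_white_noise_has_flat_spectrum(self):
        traj = noise_traj(10, 4000, 0.5, seed=61)
        result = pca(traj)
        fractions = result.explained_fraction
        n_coords = 3 * 10
        # no dominant mode: every fraction close to 1/(3n)
        assert fractions[0] < 2.5 / n_coords
        assert fractions[0] / fractions[-1] < 2.5

    def test_small_instance_matches_direct_eigendecomposition(self):
        """3-atom, 5-frame toy against an independent covariance +
        eigendecomposition oracle (and sklearn's PCA)."""
        rng = np.random.default_rng(62)
        helix = sp.make_helix(4)
        ca = sp.select_calpha(helix)
        ca3 = sp.AtomSelection(ca.indices[:3], "three")
        frames = np.repeat(helix.coords[None], 5, axis=0) + rng.normal(0, 1.0, (5, len(helix), 3))
        traj = sp.Trajectory(atom_table=helix, frames=frames)
        result = pca(traj, selection=ca3, k=3)
        x = frames[:, ca3.indices].reshape(5, -1)
        cov = np.cov(x.T, ddof=1)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(result.eigenvalues, expected, atol=1e-9)
        from sklearn.decomposition import PCA as SkPCA

        sk = SkPCA(n_components=3).fit(x)
        np.testing.assert_allclose(
            result.eigenvalues[:3], sk.explained_variance_, atol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(result.projections), np.abs(sk.transform(x)[:, :3]), atol=1e-8
        )

    def test_eigenvalue_sum_equals_trace(self):
        traj = noise_traj(8, 60, 0.4, seed=63)
        result = pca(traj)
        ca = sp.select_calpha(traj).indices
        x = traj.frames[:, ca].reshape(60, -1)
        trace = np.trace(np.cov(x.T, ddof=1))
        assert result.eigenvalues.sum() == pytest.approx(trace, rel=1e-9)

    def test_projections_are_centered(self):
        traj = noise_traj(8, 60, 0.4, seed=64)
        result = pca(traj)
        np.testing.assert_allclose(result.projections.mean(axis=0), 0.0, atol=1e-9)

    def test_too_few_frames_rejected(self, helix20):
        traj = sp.Trajectory(atom_table=helix20, frames=helix20.coords[None])
        with pytest.raises(ValueError, match="2 frames"):
            pca(traj)


class TestProjectOnto:
    def test_self_projection_reproduces(self):
        traj = noise_traj(8, 40, 0.4, seed=65)
        result = pca(traj)
        again = project_onto(result, traj, sp.select_calpha(traj))
        np.testing.assert_allclose(again, result.projections, atol=1e-9)

    def test_static_trajectory_projects_to_single_point(self):
        traj = noise_traj(8, 40, 0.4, seed=66)
        result = pca(traj)
        helix = sp.make_helix(8)
        static = sp.Trajectory(
            atom_table=helix, frames=np.repeat(helix.coords[None], 7, axis=0)
        )
        proj = project_onto(result, static, sp.select_calpha(static))
        assert np.allclose(proj, proj[0])

    def test_reduced_sigma_occupies_smaller_area(self):
        """A lower-fluctuation 'split' system covers less PC1-PC2 area than
        its 'wild type' in the wild type's essential subspace."""
        wild = noise_traj(10, 400, 0.6, seed=67)
        split = noise_traj(10, 400, 0.2, seed=68)
        result = pca(wild)
        shared_wild, shared_split = shared_calpha_selections(wild, split)
        proj_split = project_onto(result, split, shared_split)
        area_wild = ConvexHull(result.projections[:, :2]).volume
        area_split = ConvexHull(proj_split[:, :2]).volume
        assert area_split < area_wild

    def test_mismatched_selection_rejected(self):
        traj = noise_traj(8, 10, 0.3, seed=69)
        result = pca(traj)
        other = noise_traj(12, 10, 0.3, seed=70)
        with pytest.raises(ValueError, match="shared selection"):
            project_onto(result, other, sp.select_calpha(other))

    def test_joint_pca_projections_share_space(self):
        a = noise_traj(8, 30, 0.4, seed=71)
        b = noise_traj(8, 30, 0.2, seed=72)
        sel_a, sel_b = shared_calpha_selections(a, b)
        result, proj_a, proj_b = joint_pca(a, b, sel_a, sel_b)
        assert proj_a.shape == (30, 2) and proj_b.shape == (30, 2)
        combined = np.vstack([proj_a, proj_b])
        np.testing.assert_allclose(combined.mean(axis=0), 0.0, atol=1e-9)


def brute_force_gromos(mat, cutoff):
    """Literal restatement of the clustering rule for small inputs."""
    n = len(mat)
    remaining = list(range(n))
    clusters = []
    while remaining:
        best_seed, best_count = None, -1
        for i in remaining:
            count = sum(1 for j in remaining if j != i and mat[i][j] <= cutoff)
            if count > best_count:  # strict: lowest index wins ties
                best_seed, best_count = i, count
        members = [j for j in remaining if j == best_seed or mat[best_seed][j] <= cutoff]
        clusters.append(members)
        remaining = [j for j in remaining if j not in members]
    return clusters


class TestGromosClustering:
    def test_all_identical_frames_single_cluster(self, helix20):
        traj = sp.Trajectory(
            atom_table=helix20, frames=np.repeat(helix20.coords[None], 6, axis=0)
        )
        result = gromos_cluster(traj, rmsd_cutoff=1.0)
        assert result.n_clusters == 1
        assert list(result.sizes) == [6]
        assert np.all(result.labels == 0)

    def test_two_planted_conformer_groups(self, helix20, rng):
        """Inter-group RMSD >> cutoff >> intra-group noise."""
        other = helix20.with_coords(helix20.coords + rng.normal(0, 4.0, helix20.coords.shape))
        frames = []
        for k in range(7):
            frames.append(helix20.coords + rng.normal(0, 0.05, helix20.coords.shape))
        for k in range(4):
            frames.append(other.coords + rng.normal(0, 0.05, helix20.coords.shape))
        traj = sp.Trajectory(atom_table=helix20, frames=np.array(frames))
        result = gromos_cluster(traj, rmsd_cutoff=1.0)
        assert list(result.sizes) == [7, 4]
        assert len(set(result.labels[:7])) == 1
        assert len(set(result.labels[7:])) == 1

    def test_matches_brute_force_partition(self, rng):
        """<= 10 frames: partition identical to an exhaustive restatement."""
        traj = noise_traj(6, 10, 0.7, seed=73)
        mat = pairwise_rmsd_matrix(traj)
        for cutoff in (0.3, 0.6, 0.9, 1.5):
            result = gromos_cluster(traj, rmsd_cutoff=cutoff)
            expected = brute_force_gromos(mat.tolist(), cutoff)
            got = [sorted(np.nonzero(result.labels == result.labels[c[0]])[0].tolist())
                   for c in expected]
            assert [sorted(c) for c in expected] == got
            assert int(result.sizes.sum()) == traj.n_frames

    def test_representative_is_medoid(self):
        traj = noise_traj(6, 8, 0.3, seed=74)
        result = gromos_cluster(traj, rmsd_cutoff=5.0)  # one big cluster
        mat = pairwise_rmsd_matrix(traj)
        mean_rmsd = mat.sum(axis=1) / (traj.n_frames - 1)
        assert result.representatives[0] == int(np.argmin(mean_rmsd))

    def test_deterministic_under_reruns(self):
        traj = noise_traj(6, 9, 0.5, seed=75)
        a = gromos_cluster(traj, rmsd_cutoff=0.8)
        b = gromos_cluster(traj, rmsd_cutoff=0.8)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.representatives, b.representatives)

    def test_pairwise_matrix_symmetric_zero_diagonal(self):
        traj = noise_traj(5, 6, 0.4, seed=76)
        mat = pairwise_rmsd_matrix(traj)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 0.0, atol=1e-12)
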