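import numpy as np
import pytest
from scipy.stats import spearmanr

import splitperox as sp
from splitperox.stability_metrics import (
    last_fraction_window,
    rmsd_series,
    rmsf,
    trajectory_map,
    windowed_mean_displacement,
)
from splitperox.structure_io import BACKBONE_NAMES

from conftest import random_proper_rotation


def static_traj(structure, n_frames):
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    return sp.Trajectory(atom_table=structure, frames=frames)


def naive_trajectory_map(traj):
    """Independent triple-loop recomputation (small inputs only)."""
    from Bio.Data.IUPACData import atom_weights

    table = traj.atom_table
    residues = []
    for res in dict.fromkeys(int(r) for r in table.res_seq[~table.is_hetero]):
        idx = [
            i
            for i in range(len(table))
            if int(table.res_seq[i]) == res
            and not table.is_hetero[i]
            and table.name[i] in BACKBONE_NAMES
        ]
        residues.append((res, idx))
    out = np.zeros((traj.n_frames, len(residues)))
    for t in range(traj.n_frames):
        for col, (_, idx) in enumerate(residues):
            masses = [atom_weights[table.element[i].capitalize()] for i in idx]
            com_t = np.zeros(3)
            com_0 = np.zeros(3)
            for m, i in zip(masses, idx):
                com_t += m * traj.frames[t, i]
                com_0 += m * traj.frames[0, i]
            com_t /= sum(masses)
            com_0 /= sum(masses)
            out[t, col] = np.sqrt(np.sum((com_t - com_0) ** 2))
    return out


class TestRmsdSeries:
    def test_constant_trajectory_is_zero(self, helix20):
        series = rmsd_series(static_traj(helix20, 5))
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_uniform_displacement_closed_form(self, helix20):
        traj = static_traj(helix20, 3)
        frames = traj.frames.copy()
        frames[2] += np.array([2.0, 0.0, 0.0])
        series = rmsd_series(traj.with_frames(frames), fit=False)
        assert series[2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_per_frame_brute_force(self, helix20):
        traj, _ = sp.make_trajectory(helix20, sp.SyntheticSpec(n_frames=7, sigma=0.4, seed=11))
        ca = sp.select_calpha(traj).indices
        series = rmsd_series(traj)
        for t in range(traj.n_frames):
            expected = np.sqrt(
                np.mean(np.sum((traj.frames[t, ca] - traj.frames[0, ca]) ** 2, axis=1))
            )
            assert series[t] == pytest.approx(expected, abs=1e-12)

    def test_empty_selection_rejected(self, helix20):
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(static_traj(helix20, 2), selection=sp.AtomSelection(np.array([], int)))


class TestRmsf:
    def test_static_trajectory_zero(self, helix20):
        profile = rmsf(static_traj(helix20, 10))
        np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-12)
        assert list(profile.residue_numbers) == list(range(1, 21))

    def test_single_frame_warns_and_zeroes(self, helix20):
        with pytest.warns(UserWarning, match="single-frame"):
            profile = rmsf(static_traj(helix20, 1))
        np.testing.assert_allclose(profile.rmsf, 0.0)

    def test_isotropic_gaussian_closed_form(self, helix20):
        """sigma = 0.5 A per coordinate over 5000 frames gives RMSF close to
        sigma * sqrt(3) = 0.866 A."""
        traj, _ = sp.make_trajectory(helix20, sp.SyntheticSpec(n_frames=5000, sigma=0.5, seed=21))
        profile = rmsf(traj)
        assert np.mean(profile.rmsf) == pytest.approx(0.5 * np.sqrt(3), rel=0.05)

    def test_sigma_ratio_recovered(self, helix20):
        sigma = np.where(np.arange(20) < 10, 0.2, 0.6)
        traj, _ = sp.make_trajectory(helix20, sp.SyntheticSpec(n_frames=4000, sigma=sigma, seed=22))
        profile = rmsf(traj)
        ratio = profile.rmsf[10:].mean() / profile.rmsf[:10].mean()
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_mean_reference_not_larger_than_frame0(self, helix20):
        traj, _ = sp.make_trajectory(helix20, sp.SyntheticSpec(n_frames=200, sigma=0.5, seed=23))
        from_mean = rmsf(traj, reference="mean").rmsf
        from_frame0 = rmsf(traj, reference="frame0").rmsf
        assert np.all(from_mean <= from_frame0 + 1e-12)

    def test_planted_sigma_profile_rank_recovery(self, rng):
        """Per-residue RMSF recovers the planted sigma ranking."""
        helix = sp.make_helix(30)
        sigma = rng.uniform(0.1, 1.0, size=30)
        traj, manifest = sp.make_trajectory(
            helix, sp.SyntheticSpec(n_frames=2000, sigma=sigma, seed=24)
        )
        profile = rmsf(traj)
        rho = spearmanr(manifest.sigma_per_residue, profile.rmsf).statistic
        assert rho > 0.95


class TestTrajectoryMap:
    def test_frame0_row_is_zero(self, helix20):
        traj, _ = sp.make_trajectory(helix20, sp.SyntheticSpec(n_frames=5, sigma=0.3, seed=31))
        tmap = trajectory_map(traj)
        np.testing.assert_allclose(tmap.displacement[0], 0.0, atol=1e-12)

    def test_rigid_translation_removed_by_alignment(self, helix20):
        traj = static_traj(helix20, 6)
        frames = traj.frames.copy()
        for t in range(6):
            frames[t] += np.array([1.0, 2.0, -0.5]) * t
        aligned = sp.align_trajectory(traj.with_frames(frames))
        tmap = trajectory_map(aligned)
        np.testing.assert_allclose(tmap.displacement, 0.0, atol=1e-6)

    def test_three_four_five_displacement(self, helix20):
        traj = static_traj(helix20, 8)
        frames = traj.frames.copy()
        res7 = np.nonzero((helix20.res_seq == 7) & np.isin(helix20.name, BACKBONE_NAMES))[0]
        frames[5, res7] += np.array([3.0, 4.0, 0.0])
        tmap = trajectory_map(traj.with_frames(frames))
        assert tmap.displacement[5, 6] == pytest.approx(5.0, abs=1e-12)
        assert tmap.displacement[4, 6] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_triple_loop(self):
        helix = sp.make_helix(5)
        traj, _ = sp.make_trajectory(helix, sp.SyntheticSpec(n_frames=10, sigma=0.5, seed=33))
        tmap = trajectory_map(traj)
        np.testing.assert_allclose(tmap.displacement, naive_trajectory_map(traj), atol=1e-9)

    def test_residue_without_backbone_gives_nan_column(self, helix20):
        # a polymer residue holding only a side-chain atom
        table = helix20
        extra = sp.Structure(
            serial=np.concatenate([table.serial, [999]]),
            name=np.concatenate([table.name, ["SG"]]),
            element=np.concatenate([table.element, ["S"]]),
            res_name=np.concatenate([table.res_name, ["CYS"]]),
            res_seq=np.concatenate([table.res_seq, [21]]),
            chain=np.concatenate([table.chain, ["A"]]),
            is_hetero=np.concatenate([table.is_hetero, [False]]),
            coords=np.vstack([table.coords, [[50.0, 0.0, 0.0]]]),
        )
        traj = static_traj(extra, 3)
        with pytest.warns(UserWarning, match="no backbone"):
            tmap = trajectory_map(traj)
        assert np.all(np.isnan(tmap.displacement[:, -1]))
        assert np.all(np.isfinite(tmap.displacement[:, :-1]))


class TestWindowedDisplacement:
    def test_constant_matrix(self, helix20):
        traj = static_traj(helix20, 4)
        tmap = trajectory_map(traj)
        tmap.displacement[:] = 1.7
        disp = windowed_mean_displacement(tmap, (0, 4))
        assert disp.mean == pytest.approx(1.7)
        assert disp.sd == pytest.approx(0.0)

    def test_two_frame_window_statistics(self, helix20):
        traj = static_traj(helix20, 2)
        tmap = trajectory_map(traj)
        tmap.displacement[0, :] = 1.0
        tmap.displacement[1, :] = 2.0
        disp = windowed_mean_displacement(tmap, (0, 2))
        assert disp.mean == pytest.approx(1.5)
        assert disp.sd == pytest.approx(np.std([1.0, 2.0], ddof=1))

    def test_ramping_sigma_increases_late_window(self, helix20):
        sigma_series = np.concatenate([np.full(100, 0.1), np.full(100, 0.8)])
        frames = np.repeat(helix20.coords[None], 200, axis=0)
        rng = np.random.default_rng(44)
        for t in range(200):
            frames[t] += rng.normal(0, sigma_series[t], helix20.coords.shape)
        tmap = trajectory_map(sp.Trajectory(atom_table=helix20, frames=frames))
        early = windowed_mean_displacement(tmap, (1, 100))
        late = windowed_mean_displacement(tmap, (100, 200))
        assert late.mean > early.mean

    def test_empty_or_out_of_range_window_rejected(self, helix20):
        tmap = trajectory_map(static_traj(helix20, 3))
        with pytest.raises(ValueError):
            windowed_mean_displacement(tmap, (2, 2))
        with pytest.raises(ValueError):
            windowed_mean_displacement(tmap, (0, 99))

    def test_last_fraction_window(self):
        assert last_fraction_window(100, 0.4) == (60, 100)
        assert last_fraction_window(5, 1.0) == (0, 5)


def test_statistics_invariant_to_common_rigid_transform(helix20, rng):
    """Applying one rigid transform to every frame before alignment leaves
    RMSF and the trajectory map unchanged."""
    traj, _ = sp.make_trajectory(helix20, sp.SyntheticSpec(n_frames=50, sigma=0.4, seed=55))
    rot = random_proper_rotation(rng)
    shift = rng.normal(0, 10, 3)
    moved = traj.with_frames(traj.frames @ rot.T + shift)
    a = sp.align_trajectory(traj)
    b = sp.align_trajectory(moved, reference=0)
    np.testing.assert_allclose(rmsf(b).rmsf, rmsf(a).rmsf, atol=1e-9)
    np.testing.assert_allclose(
        trajectory_map(b).displacement, trajectory_map(a).displacement, atol=1e-9
    )
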