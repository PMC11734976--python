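"""Superposition and the RMSD / RMSF / Rg metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_trajectory
from mnp_funnel.synthetic_data import (
    HarmonicTrajModel,
    gen_trajectory,
    helix_backbone,
    random_rotation,
)
from mnp_funnel.traj_analysis import (
    DegenerateGeometryError,
    Selection,
    apply_transform,
    kabsch_superpose,
    radius_of_gyration,
    rmsd_series,
    rmsf,
)


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(7, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        true_rot = random_rotation(rng)
        moved = pts @ true_rot.T + np.array([3.0, -2.0, 7.0])
        rot, trans, rmsd = kabsch_superpose(moved, pts)
        assert rmsd <= 1e-6
        np.testing.assert_allclose(
            apply_transform(moved, rot, trans), pts, atol=1e-9
        )

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        # near-planar clouds tempt the reflection branch
        a = rng.normal(size=(6, 3)) * np.array([1.0, 1.0, 1e-4])
        b = rng.normal(size=(6, 3))
        rot, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_solver(self):
        # scipy's align_vectors solves the same weighted Wahba problem
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            rot, trans, rmsd = kabsch_superpose(a, b)
            sp_rot, _ = Rotation.align_vectors(
                b - b.mean(axis=0), a - a.mean(axis=0)
            )
            aligned = (a - a.mean(axis=0)) @ sp_rot.as_matrix().T
            sp_rmsd = np.sqrt(((aligned - (b - b.mean(axis=0))) ** 2)
                              .sum(axis=1).mean())
            assert rmsd == pytest.approx(sp_rmsd, abs=1e-4)

    def test_no_sampled_rotation_beats_kabsch(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        _, _, best = kabsch_superpose(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        for _ in range(2000):
            rot = random_rotation(rng)
            rmsd = np.sqrt(((ac @ rot.T - bc) ** 2).sum(axis=1).mean())
            assert rmsd >= best - 1e-12

    def test_weighted_fit_prefers_heavy_points(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5.0, 5.0, 0.0]])
        b = a.copy()
        b[3] += [0.0, 0.0, 2.0]
        w_hi = np.array([1.0, 1.0, 1.0, 100.0])
        _, _, rmsd_hi = kabsch_superpose(a, b, w_hi)
        _, _, rmsd_lo = kabsch_superpose(a, b, np.ones(4))
        assert rmsd_hi != pytest.approx(rmsd_lo)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_zero_sigma_series_is_zero(self):
        traj = gen_trajectory(
            HarmonicTrajModel(reference=helix_backbone(10), n_frames=5)
        )
        np.testing.assert_allclose(rmsd_series(traj).values, 0.0, atol=1e-10)

    def test_single_displaced_atom_closed_form(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(100, 3)) * 5.0
        frame = ref.copy()
        frame[0] += [1.0, 0.0, 0.0]
        traj = make_trajectory(np.stack([ref, frame]))
        # fit on the 99 undisturbed atoms so the transform is identity
        series = rmsd_series(
            traj, reference=0, fit_selection=np.arange(1, 100),
            calc_selection=np.arange(100),
        )
        assert series.values[1] == pytest.approx(0.1, abs=1e-9)

    def test_matches_direct_formula_oracle(self):
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=helix_backbone(15), per_atom_sd=0.4,
                n_frames=10, seed=6,
            )
        )
        series = rmsd_series(traj)
        ref = traj.coords[0]
        for t in range(traj.n_frames):
            rot, trans, _ = kabsch_superpose(traj.coords[t], ref)
            moved = apply_transform(traj.coords[t], rot, trans)
            naive = np.sqrt(((moved - ref) ** 2).sum(axis=1).mean())
            assert series.values[t] == pytest.approx(naive, abs=1e-6)

    def test_matches_mdtraj(self, tmp_path):
        import mdtraj

        from mnp_funnel.synthetic_data import toy_complex
        from mnp_funnel.traj_analysis import write_pdb

        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=toy_complex(n_residues=30, ligand_anchor_resid=15),
                per_atom_sd=0.5, n_frames=20, seed=14,
            )
        )
        path = tmp_path / "cross.pdb"
        write_pdb(traj, path)
        md = mdtraj.load(str(path))
        theirs = mdtraj.rmsd(md, md, 0) * 10.0  # nm -> Å
        ours = rmsd_series(traj, reference=0).values
        np.testing.assert_allclose(ours, theirs, atol=2e-3)

    def test_summary_is_mean_and_sd(self):
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=helix_backbone(12), per_atom_sd=0.3,
                n_frames=20, seed=7,
            )
        )
        series = rmsd_series(traj)
        assert series.mean == pytest.approx(np.mean(series.values))
        assert series.sd == pytest.approx(np.std(series.values))


class TestRmsf:
    def test_zero_sigma_all_zero(self):
        traj = gen_trajectory(
            HarmonicTrajModel(reference=helix_backbone(8), n_frames=4)
        )
        np.testing.assert_allclose(rmsf(traj).values, 0.0, atol=1e-10)

    def test_isotropic_sigma_recovery(self):
        # RMSF of an isotropic Gaussian with per-coordinate sd sigma is
        # sigma * sqrt(3); 10^4 frames on a large helix keeps both the
        # sampling error and the fitting-absorbed variance below 2%
        sigma = 0.5
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=helix_backbone(100), per_atom_sd=sigma,
                n_frames=10_000, seed=8,
            )
        )
        values = rmsf(traj).values
        expected = sigma * np.sqrt(3.0)
        assert values.mean() == pytest.approx(expected, rel=0.02)

    def test_heterogeneous_sigma_ordering(self):
        sds = np.concatenate([np.full(30, 0.2), np.full(30, 0.8)])
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=helix_backbone(60), per_atom_sd=sds,
                n_frames=2000, seed=9,
            )
        )
        values = rmsf(traj).values
        assert values[:30].mean() < values[30:].mean()

    def test_parseval_identity(self):
        # mean squared RMSF over atoms == mean over frames of the mean
        # squared deviation from the mean structure
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=helix_backbone(20), per_atom_sd=0.4,
                n_frames=50, seed=10,
            )
        )
        from mnp_funnel.traj_analysis import superpose_frames

        fitted = superpose_frames(traj)
        mean = fitted.mean(axis=0)
        per_atom_msf = ((fitted - mean) ** 2).sum(axis=2).mean(axis=0)
        per_frame_msd = ((fitted - mean) ** 2).sum(axis=2).mean(axis=1)
        assert per_atom_msf.mean() == pytest.approx(
            per_frame_msd.mean(), rel=1e-8
        )
        np.testing.assert_allclose(
            rmsf(traj).values, np.sqrt(per_atom_msf), atol=1e-10
        )

    def test_active_site_residue_aggregation(self):
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=helix_backbone(170), per_atom_sd=0.3,
                n_frames=30, seed=11,
            )
        )
        site = [19, 24, 41, 99, 103, 104, 162]
        profile = rmsf(traj, Selection(resids=site), aggregate_by_residue=True)
        assert list(profile.by_residue.index) == site
        assert (profile.by_residue > 0).all()

    def test_single_frame_rejected(self):
        traj = helix_backbone(5)
        with pytest.raises(ValueError):
            rmsf(traj)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        traj = make_trajectory(np.zeros((1, 1, 3)))
        assert radius_of_gyration(traj).values[0] == pytest.approx(0.0)

    def test_two_unit_masses_closed_form(self):
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        traj = make_trajectory(coords)  # equal masses
        assert radius_of_gyration(traj).values[0] == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(1, 50, 3)) * 8.0
        elements = rng.choice(["C", "N", "O", "S"], size=50)
        traj = make_trajectory(coords, elements=elements)
        masses = traj.atoms["mass"].to_numpy()
        com = (masses[:, None] * coords[0]).sum(axis=0) / masses.sum()
        naive = np.sqrt(
            (masses * ((coords[0] - com) ** 2).sum(axis=1)).sum() / masses.sum()
        )
        assert radius_of_gyration(traj).values[0] == pytest.approx(
            naive, abs=1e-10
        )

    def test_rigid_motion_invariance(self):
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=helix_backbone(20), per_atom_sd=0.0, n_frames=6,
                rigid_motion="random", seed=13,
            )
        )
        values = radius_of_gyration(traj).values
        np.testing.assert_allclose(values, values[0], atol=1e-6)
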