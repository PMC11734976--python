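"""Shrake–Rupley SASA, hydrogen-bond counting, and contact timelines."""

import numpy as np
import pytest

from conftest import make_trajectory
from mnp_funnel.synthetic_data import (
    HarmonicTrajModel,
    gen_trajectory,
    helix_backbone,
    toy_complex,
)
from mnp_funnel.traj_analysis import (
    Selection,
    contact_timeline,
    hbond_count_frame,
    hbond_count_series,
    ionic_contact_series,
    sasa_frame,
    sasa_series,
    sphere_points,
)
from mnp_funnel.traj_analysis.core import UnknownElementError, element_radius


class TestSpherePoints:
    def test_unit_norm(self):
        pts = sphere_points(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_quasi_uniform_centroid(self):
        assert np.abs(sphere_points(960).mean(axis=0)).max() < 0.01


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        # carbon r=1.7 plus probe 1.4: area = 4*pi*3.1^2 = 120.76 Å^2
        area = sasa_frame(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)
        assert area[0] == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        total = sasa_frame(coords, radii, 1.4, 960).sum()
        isolated = sum(
            sasa_frame(np.zeros((1, 3)), np.array([r]), 1.4, 960)[0]
            for r in radii
        )
        assert total == pytest.approx(isolated, rel=1e-9)

    def test_overlapping_pair_matches_monte_carlo(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        radii = np.array([1.7, 1.7])
        probe = 1.4
        ours = sasa_frame(coords, radii, probe, 960).sum()
        rng = np.random.default_rng(0)
        mc_total = 0.0
        n_mc = 500_000
        dressed = radii + probe
        for i in range(2):
            dirs = rng.normal(size=(n_mc, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            pts = coords[i] + dressed[i] * dirs
            j = 1 - i
            outside = ((pts - coords[j]) ** 2).sum(axis=1) > dressed[j] ** 2
            mc_total += outside.mean() * 4 * np.pi * dressed[i] ** 2
        assert ours == pytest.approx(mc_total, rel=0.02)

    def test_monotone_decrease_on_approach(self):
        radii = np.array([1.7, 1.7])
        seps = [6.5, 5.0, 4.0, 3.0, 2.0, 1.0]
        areas = [
            sasa_frame(
                np.array([[0.0, 0, 0], [d, 0.0, 0.0]]), radii, 1.4, 960
            ).sum()
            for d in seps
        ]
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))
        isolated = 2 * sasa_frame(np.zeros((1, 3)), radii[:1], 1.4, 960)[0]
        assert all(a <= isolated + 1e-9 for a in areas)

    def test_series_unit_conversion(self):
        traj = make_trajectory(np.zeros((1, 1, 3)), elements=["C"])
        series = sasa_series(traj, n_sphere_points=960)
        assert series.unit == "nm²"
        assert series.values[0] == pytest.approx(
            4 * np.pi * 3.1**2 / 100.0, rel=0.01
        )

    def test_rigid_motion_invariance(self):
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=helix_backbone(15), per_atom_sd=0.0, n_frames=4,
                rigid_motion="random", seed=1,
            )
        )
        values = sasa_series(traj, n_sphere_points=240).values
        np.testing.assert_allclose(values, values[0], atol=1e-6)

    def test_unknown_element_named(self):
        with pytest.raises(UnknownElementError, match="Xx"):
            element_radius("Xx")

    def test_negative_probe_rejected(self):
        with pytest.raises(ValueError):
            sasa_frame(np.zeros((1, 3)), np.array([1.7]), -0.1)


def _water_pair(d_oo=2.8, angle_deg=180.0):
    """O1-H1...O2 geometry with given O...O distance and D-H...A angle."""
    o1 = np.array([0.0, 0.0, 0.0])
    h1 = np.array([0.96, 0.0, 0.0])
    # place acceptor so that the H...A direction makes the requested
    # angle with the H->D direction
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve for |h-a| so that |o1-a| = d_oo
    from scipy.optimize import brentq

    def f(t):
        return np.linalg.norm(h1 + t * direction - o1) - d_oo

    t = brentq(f, 0.1, 10.0)
    o2 = h1 + t * direction
    coords = np.stack([o1, h1, o2])[None]
    return make_trajectory(coords, elements=["O", "H", "O"], resids=[1, 1, 2])


class TestHbonds:
    def test_canonical_geometry_counts_one(self):
        traj = _water_pair(2.8, 180.0)
        assert hbond_count_series(traj).values.tolist() == [1.0]

    def test_distance_cutoff_excludes(self):
        traj = _water_pair(4.0, 180.0)
        assert hbond_count_series(traj, d_cutoff=3.5).values.tolist() == [0.0]

    def test_angle_cutoff_excludes(self):
        bent = _water_pair(2.8, 120.0)  # 60° off linear
        ok = _water_pair(2.8, 160.0)  # 20° off linear
        assert hbond_count_series(bent, angle_cutoff=30.0).values[0] == 0.0
        assert hbond_count_series(ok, angle_cutoff=30.0).values[0] == 1.0

    def test_heavy_atom_mode(self):
        traj = _water_pair(2.8, 120.0)  # bad angle, good distance
        donors = np.array([0])  # heavy-atom-only: distance criterion alone
        acceptors = np.array([2])
        series = hbond_count_series(traj, donors=donors, acceptors=acceptors)
        assert series.values[0] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        n_heavy, n_h = 30, 20
        coords = rng.uniform(0, 12.0, size=(n_heavy + n_h, 3))
        elements = ["O"] * 15 + ["N"] * 15 + ["H"] * n_h
        donors = np.array(
            [(i, n_heavy + k) for k, i in enumerate(
                rng.integers(0, n_heavy, size=n_h))]
        )
        # put each H within covalent range of its donor
        for d, h in donors:
            offset = rng.normal(size=3)
            coords[h] = coords[d] + 0.98 * offset / np.linalg.norm(offset)
        acceptors = np.arange(n_heavy)
        count = hbond_count_frame(coords, donors, acceptors, 3.5, 30.0)

        oracle = 0
        for d, h in donors:
            for a in acceptors:
                if a == d:
                    continue
                if np.linalg.norm(coords[a] - coords[d]) > 3.5:
                    continue
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle >= 150.0:
                    oracle += 1
        assert count == oracle

    def test_no_donors_rejected(self):
        traj = make_trajectory(np.zeros((1, 3, 3)), elements=["C", "C", "C"])
        with pytest.raises(ValueError):
            hbond_count_series(traj)


class TestContacts:
    def test_planted_schedule_exact_percentage(self):
        # ligand atom approaches residue 2 in exactly 50 of 100 frames
        n_frames = 100
        coords = np.zeros((n_frames, 3, 3))
        coords[:, 0] = [0.0, 0.0, 0.0]  # residue 1
        coords[:, 1] = [20.0, 0.0, 0.0]  # residue 2
        for t in range(n_frames):
            near = t % 2 == 0
            coords[t, 2] = [20.0, 3.0, 0.0] if near else [100.0, 0.0, 0.0]
        traj = make_trajectory(coords, resids=[1, 2, 9])
        timeline = contact_timeline(
            traj, ligand_selection=np.array([2]), d_cutoff=4.5
        )
        assert timeline.percentages[2] == pytest.approx(50.0)
        assert timeline.percentages[1] == pytest.approx(0.0)
        assert not timeline.matrix[list(timeline.resids).index(1)].any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        traj = gen_trajectory(
            HarmonicTrajModel(
                reference=toy_complex(n_residues=25, ligand_anchor_resid=12),
                per_atom_sd=1.0, n_frames=15, seed=4,
            )
        )
        cutoff = 6.0
        timeline = contact_timeline(
            traj, Selection(resnames=["LIG"]), d_cutoff=cutoff
        )
        lig = traj.atoms.index[traj.atoms["resname"] == "LIG"].to_numpy()
        for k, resid in enumerate(timeline.resids):
            res_atoms = traj.atoms.index[
                (traj.atoms["resid"] == resid)
                & (traj.atoms["resname"] != "LIG")
            ].to_numpy()
            for t in range(traj.n_frames):
                expected = any(
                    np.linalg.norm(traj.coords[t, i] - traj.coords[t, j])
                    <= cutoff
                    for i in res_atoms
                    for j in lig
                )
                assert timeline.matrix[k, t] == expected

    def test_ionic_channel_centroid_distance(self):
        coords = np.zeros((2, 4, 3))
        coords[0, 2:] = [[4.0, 0, 0], [6.0, 0, 0]]  # centroid 5.0 -> contact
        coords[1, 2:] = [[8.0, 0, 0], [10.0, 0, 0]]  # centroid 9.0 -> none
        traj = make_trajectory(coords, elements=["N", "N", "O", "O"])
        series = ionic_contact_series(
            traj, np.array([0, 1]), np.array([2, 3]), d_cutoff=5.0
        )
        assert series.tolist() == [True, False]
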