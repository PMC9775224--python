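"""Structural stage: distances, RMSD, SASA, torsions, decoupled PCA, landscapes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phlink.conformation import (
    ConformationEnsemble,
    central_structure,
    com_distance,
    contact_area,
    dissociation_mask,
    histogram_1d,
    interface_dihedral,
    landscape,
    pca_decoupled,
    rmsd,
    sasa,
    select_atoms,
)
from phlink.constants import rt
from phlink.synthetic import generate_dimer_ensemble


def _rand_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(size=3)
    return R, t


class TestComDistance:
    def test_identical_selections_zero(self):
        frame = np.random.default_rng(0).normal(size=(10, 3))
        sel = np.arange(5)
        assert com_distance(frame, sel, sel) == 0.0

    def test_weighted_arithmetic(self):
        frame = np.array([[0, 0, 0], [3, 0, 0], [6, 0, 0]], float)
        d = com_distance(frame, np.array([0, 1]), np.array([2]),
                         masses=np.ones(3))
        assert d == pytest.approx(4.5)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(size=(20, 3))
        a, b = np.arange(10), np.arange(10, 20)
        R, t = _rand_rigid(2)
        d0 = com_distance(frame, a, b)
        d1 = com_distance(frame @ R.T + t, a, b)
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            com_distance(np.zeros((3, 3)), np.array([], int), np.array([0]))


class TestRmsd:
    def test_zero_on_self_and_rotated_copy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-12)
        R, t = _rand_rigid(4)
        assert rmsd(x @ R.T + t, x) == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_rotation_search(self):
        # two 4-point toy configurations; independent minimisation over
        # rotation vectors (coarse random restarts + local refinement)
        from scipy.optimize import minimize

        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        y = np.array([[0.1, 0, 0], [1.05, 0.2, 0], [-0.1, 0.9, 0.1], [0, 0.1, 1.1]])
        xc = x - x.mean(0)
        yc = y - y.mean(0)

        def objective(rv):
            R = Rotation.from_rotvec(rv).as_matrix()
            return float(np.sqrt(((yc @ R.T - xc) ** 2).sum(1).mean()))

        rng = np.random.default_rng(5)
        best = np.inf
        for _ in range(30):
            res = minimize(objective, rng.normal(size=3), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        assert rmsd(y, x) == pytest.approx(best, abs=1e-6)


class TestDissociation:
    def test_reference_copies_all_retained(self):
        ens = generate_dimer_ensemble(angles_deg=[0.0] * 5, seed=0)
        ref = ens.frames[0]
        a = select_atoms(ens.atoms, "chain A")
        b = select_atoms(ens.atoms, "chain B")
        mask = dissociation_mask(ens, ref, selection_A=a, selection_B=b)
        assert mask.all()

    def test_translated_partner_excluded_at_defaults(self):
        shifts = [[0, 0, 0], [0, 0, 0], [5.0, 0, 0], [0, 0, 0], [4.0, 0, 0]]
        ens = generate_dimer_ensemble(
            angles_deg=[0.0] * 5, extra_translations=shifts, seed=1
        )
        ref = generate_dimer_ensemble(angles_deg=[0.0], seed=1).frames[0]
        a = select_atoms(ens.atoms, "chain A")
        b = select_atoms(ens.atoms, "chain B")
        mask = dissociation_mask(ens, ref, selection_A=a, selection_B=b)
        np.testing.assert_array_equal(mask, [True, True, False, True, False])

    def test_idempotent(self):
        ens = generate_dimer_ensemble(
            angles_deg=[0.0] * 4,
            extra_translations=[[0, 0, 0], [9, 0, 0], [0, 0, 0], [9, 0, 0]],
            seed=2,
        )
        ref = ens.frames[0]
        a = select_atoms(ens.atoms, "chain A")
        b = select_atoms(ens.atoms, "chain B")
        m1 = dissociation_mask(ens, ref, selection_A=a, selection_B=b)
        sub = ConformationEnsemble(atoms=ens.atoms, frames=ens.frames[m1])
        m2 = dissociation_mask(sub, ref, selection_A=a, selection_B=b)
        assert m2.all()

    def test_mask_feeds_occupancy_filtering(self):
        from phlink.occupancy import OccupancyTrajectory, SiteDefinition, apply_frame_mask

        ens = generate_dimer_ensemble(
            angles_deg=[0.0] * 4,
            extra_translations=[[0, 0, 0], [9, 0, 0], [0, 0, 0], [9, 0, 0]],
            seed=3,
        )
        ref = ens.frames[0]
        a = select_atoms(ens.atoms, "chain A")
        b = select_atoms(ens.atoms, "chain B")
        mask = dissociation_mask(ens, ref, selection_A=a, selection_B=b)
        traj = OccupancyTrajectory(
            sites=(SiteDefinition("A:ASP1", "acid"), SiteDefinition("B:ASP1", "acid")),
            times=np.arange(1.0, 5.0),
            occupancies=np.ones((4, 2), dtype=np.uint8),
            pH=5.0,
            form="dimer",
        )
        out = apply_frame_mask(traj, mask)
        np.testing.assert_array_equal(out.frame_mask, [True, False, True, False])


class TestCentralStructure:
    def test_identical_frames_tie_break(self):
        frame = np.random.default_rng(6).normal(size=(9, 3))
        ens = _ens(np.repeat(frame[None], 4, axis=0))
        assert central_structure(ens) == 0

    def test_outlier_not_chosen(self):
        rng = np.random.default_rng(7)
        frame = rng.normal(size=(9, 3))
        frames = np.repeat(frame[None], 5, axis=0)
        frames += rng.normal(scale=0.01, size=frames.shape)
        frames[2] += 5.0 * rng.normal(size=(9, 3))
        assert central_structure(_ens(frames)) != 2

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        frames = rng.normal(size=(12, 6, 3))
        ens = _ens(frames)
        idx = central_structure(ens)
        n = len(frames)
        d2 = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d2[i, j] = rmsd(frames[i], frames[j]) ** 2
        assert idx == int(np.argmin(d2.mean(axis=1)))


def _ens(frames):
    from phlink.conformation import AtomRecord

    atoms = [
        AtomRecord(name="CA", resname="ALA", resid=i + 1, chain="A")
        for i in range(frames.shape[1])
    ]
    return ConformationEnsemble(atoms=atoms, frames=frames)


class TestSasa:
    def test_single_atom_sphere(self):
        areas, total = sasa(np.zeros((1, 3)), np.array([0.17]))
        expected = 4 * np.pi * (0.17 + 0.14) ** 2
        assert total == pytest.approx(expected, rel=0.005)

    def test_far_separated_additivity(self):
        coords = np.array([[0, 0, 0], [10.0, 0, 0]])
        radii = np.array([0.17, 0.15])
        _, total = sasa(coords, radii)
        _, a = sasa(coords[:1], radii[:1])
        _, b = sasa(coords[1:], radii[1:])
        assert total == pytest.approx(a + b, rel=1e-12)

    def test_two_overlapping_spheres_closed_form(self):
        # equal expanded radii R at centre distance d: each cap height
        # h = R - d/2, exposed area per sphere = 4 pi R^2 - 2 pi R h
        r = 0.17
        probe = 0.14
        R = r + probe
        d = 0.35
        coords = np.array([[0, 0, 0], [d, 0, 0]])
        _, total = sasa(coords, np.array([r, r]), probe=probe, n_sphere_points=4000)
        h = R - d / 2
        expected = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)
        assert total == pytest.approx(expected, rel=0.01)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(scale=0.4, size=(50, 3))
        radii = np.full(50, 0.16)
        _, t1 = sasa(coords, radii, n_sphere_points=960)
        _, t2 = sasa(coords, radii, n_sphere_points=1920)
        assert abs(t1 - t2) / t2 < 0.005

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([0.17]), n_sphere_points=16)


class TestContactArea:
    def test_distant_partners_zero(self):
        coords = np.vstack([np.zeros((3, 3)), np.zeros((3, 3)) + [8.0, 0, 0]])
        coords[:3] += np.random.default_rng(10).normal(scale=0.1, size=(3, 3))
        radii = np.full(6, 0.17)
        c = contact_area(coords, radii, np.arange(3), np.arange(3, 6))
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_in_partners(self):
        rng = np.random.default_rng(11)
        coords = np.vstack([rng.normal(scale=0.3, size=(4, 3)),
                            rng.normal(scale=0.3, size=(4, 3)) + [0.5, 0, 0]])
        radii = np.full(8, 0.16)
        a = contact_area(coords, radii, np.arange(4), np.arange(4, 8))
        b = contact_area(coords, radii, np.arange(4, 8), np.arange(4))
        assert a == pytest.approx(b, abs=1e-12)

    def test_two_touching_spheres_closed_form(self):
        r, probe, d = 0.17, 0.14, 0.35
        R = r + probe
        coords = np.array([[0, 0, 0], [d, 0, 0]])
        radii = np.array([r, r])
        buried = contact_area(
            coords, radii, np.array([0]), np.array([1]),
            convention="full", n_sphere_points=4000,
        )
        h = R - d / 2
        expected = 2 * (2 * np.pi * R * h)  # both buried caps
        assert buried == pytest.approx(expected, rel=0.01)
        half = contact_area(
            coords, radii, np.array([0]), np.array([1]),
            convention="half", n_sphere_points=4000,
        )
        assert half == pytest.approx(buried / 2, abs=1e-12)

    def test_overlapping_selections_rejected(self):
        with pytest.raises(ValueError):
            contact_area(
                np.zeros((4, 3)), np.full(4, 0.1), np.array([0, 1]), np.array([1, 2])
            )


class TestDihedral:
    def test_trans_and_cis(self):
        p1, p2, p3 = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        assert interface_dihedral(p1, p2, p3, [1, -1, 0]) == pytest.approx(180.0)
        assert interface_dihedral(p1, p2, p3, [1, 1, 0]) == pytest.approx(0.0, abs=1e-10)

    def test_chirality_negation(self):
        p = [np.array(v, float) for v in
             ([0, 1, 0], [0, 0, 0], [1, 0, 0], [1.3, 0.4, 0.8])]
        ang = interface_dihedral(*p)
        mirrored = [q * np.array([1, 1, -1]) for q in p]
        assert interface_dihedral(*mirrored) == pytest.approx(-ang, abs=1e-10)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            interface_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_programmed_rotation_tracked(self):
        # chain B spins about the interchain (x) axis, so the torsion
        # defined across the interface must track the programmed angle
        angles = np.linspace(0.0, 90.0, 7)
        ens = generate_dimer_ensemble(
            angles_deg=angles, axis=(1.0, 0.0, 0.0), translation=(1.5, 0.0, 0.0),
            seed=12,
        )
        a_idx = select_atoms(ens.atoms, "chain A")
        b_idx = select_atoms(ens.atoms, "chain B")
        measured = []
        for frame in ens.frames:
            a = frame[a_idx]
            b = frame[b_idx]
            p1 = a[2 * a_idx.size // 3 :].mean(0)  # off-axis group on A
            p2 = a.mean(0)
            p3 = b.mean(0)
            p4 = b[2 * b_idx.size // 3 :].mean(0)  # off-axis group on B
            measured.append(interface_dihedral(p1, p2, p3, p4))
        diffs = np.abs(np.diff(measured))
        np.testing.assert_allclose(diffs, np.diff(angles), atol=2.0)


class TestPCA:
    def test_identical_frames_zero_variance(self):
        ens = generate_dimer_ensemble(angles_deg=[0.0] * 6, seed=13)
        fit = select_atoms(ens.atoms, "chain A")
        tr = select_atoms(ens.atoms, "chain B")
        model = pca_decoupled(ens, fit, tr, ens.frames[0])
        assert np.all(model.explained_variance_ratio < 1e-20)

    def test_whole_system_rigid_motion_removed(self):
        angles = np.linspace(0, 60, 8)
        ens = generate_dimer_ensemble(angles_deg=angles, seed=14)
        fit = select_atoms(ens.atoms, "chain A")
        tr = select_atoms(ens.atoms, "chain B")
        model = pca_decoupled(ens, fit, tr, ens.frames[0])
        rng = np.random.default_rng(15)
        moved = ens.frames.copy()
        for k in range(moved.shape[0]):
            R, t = _rand_rigid(100 + k)
            moved[k] = moved[k] @ R.T + t
        proj2 = model.transform(moved)
        np.testing.assert_allclose(proj2, model.projections, atol=1e-8)

    def test_one_axis_rotation_dominates_pc1(self):
        angles = np.linspace(0, 60, 24)
        ens = generate_dimer_ensemble(angles_deg=angles, seed=16)
        fit = select_atoms(ens.atoms, "chain A")
        tr = select_atoms(ens.atoms, "chain B")
        model = pca_decoupled(ens, fit, tr, ens.frames[0])
        assert model.explained_variance_ratio[0] >= 0.90
        pc1 = model.projections[:, 0]
        assert np.all(np.diff(pc1) > 0) or np.all(np.diff(pc1) < 0)

    def test_components_orthonormal_and_reconstruction(self):
        angles = np.linspace(0, 45, 10)
        ens = generate_dimer_ensemble(angles_deg=angles, noise_sigma=0.01, seed=17)
        fit = select_atoms(ens.atoms, "chain A")
        tr = select_atoms(ens.atoms, "chain B")
        model = pca_decoupled(ens, fit, tr, ens.frames[0])
        G = model.components @ model.components.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-10)
        from phlink.conformation import _superposed_transform_coords

        X = _superposed_transform_coords(ens.frames, ens.frames[0], fit, tr)
        recon = model.projections @ model.components + model.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_overlapping_selections_rejected(self):
        ens = generate_dimer_ensemble(angles_deg=[0.0, 10.0], seed=18)
        idx = select_atoms(ens.atoms, "chain A")
        with pytest.raises(ValueError, match="disjoint"):
            pca_decoupled(ens, idx, idx, ens.frames[0])


class TestLandscape:
    def test_minimum_zero_at_density_max(self):
        rng = np.random.default_rng(19)
        pts = rng.normal(size=(2_000, 2))
        ls = landscape(pts, mesh=0.1)
        assert ls.free_energy.min() == 0.0
        i, j = np.unravel_index(np.argmax(ls.density), ls.density.shape)
        assert ls.free_energy[i, j] == 0.0
        assert np.all(ls.free_energy >= 0.0)

    def test_kT_at_density_over_e(self):
        rng = np.random.default_rng(20)
        pts = rng.normal(size=(5_000, 2))
        ls = landscape(pts, mesh=0.05, temperature=300.0)
        target = ls.density.max() / np.e
        k = np.argmin(np.abs(ls.density - target))
        f = ls.free_energy.ravel()[k]
        p = ls.density.ravel()[k]
        expected = -rt(300.0) * np.log(p / ls.density.max())
        assert f == pytest.approx(expected, abs=1e-12)
        assert f == pytest.approx(rt(300.0), rel=0.05)

    def test_symmetric_double_well(self):
        rng = np.random.default_rng(21)
        n = 20_000
        a = rng.normal(loc=(-3.0, 0.0), scale=0.5, size=(n // 2, 2))
        b = rng.normal(loc=(3.0, 0.0), scale=0.5, size=(n // 2, 2))
        pts = np.vstack([a, b])
        ls = landscape(pts, mesh=0.1, bandwidth=(0.3, 0.3))
        mid = ls.x_edges.searchsorted(0.0)
        f_left = ls.free_energy[:mid].min()
        f_right = ls.free_energy[mid:].min()
        assert abs(f_left - f_right) < 0.1 * rt(300.0)

    def test_bandwidth_decreases_with_n(self):
        from phlink.conformation import _kde_bandwidth

        assert _kde_bandwidth(1.0, 10_000) < _kde_bandwidth(1.0, 100)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            landscape(np.zeros((10, 2)), mesh=0.1)


class TestHistogram:
    def test_normalisation(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=3_000)
        grid, dens = histogram_1d(x)
        mass = np.trapezoid(dens, grid)
        assert mass == pytest.approx(1.0, abs=0.01)


class TestSelections:
    def test_grammar(self):
        ens = generate_dimer_ensemble(angles_deg=[0.0], n_residues=5, seed=23)
        atoms = ens.atoms
        assert len(select_atoms(atoms, "chain A")) == 15
        assert len(select_atoms(atoms, "backbone")) == 30
        assert len(select_atoms(atoms, "chain B and name CA")) == 5
        assert len(select_atoms(atoms, "resid 2-3 and chain A")) == 6
        with pytest.raises(ValueError):
            select_atoms(atoms, "protein")
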