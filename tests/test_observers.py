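"""Observer placement and the six feature values."""

import numpy as np
import pytest

from esim.chem import Molecule
from esim.observers import (acceptor_feature, compute_features,
                            coulombic_energy, donor_feature, place_observers,
                            steric_distance, tessellate_sphere,
                            _surface_distances)
from esim.fixtures import prepare


def united_atom(radius=1.7, charge=0.0, element="C", pos=(0.0, 0.0, 0.0)):
    return Molecule(name="atom", elements=[element],
                    coords=np.array([pos], dtype=float), bonds=[],
                    charges=np.array([charge]), radii=np.array([radius]))


class TestTessellation:
    def test_points_on_sphere_and_deterministic(self):
        c = np.array([1.0, -2.0, 3.0])
        a = tessellate_sphere(c, 10.0, 1.0)
        b = tessellate_sphere(c, 10.0, 1.0)
        assert np.array_equal(a, b)
        r = np.linalg.norm(a - c, axis=1)
        assert np.abs(r - 10.0).max() < 1e-9

    def test_count_matches_area_estimate(self):
        pts = tessellate_sphere(np.zeros(3), 10.0, 1.0)
        expected = 4 * np.pi * 100  # area / spacing^2
        assert abs(len(pts) - expected) / expected < 0.25

    def test_nearest_neighbor_spacing(self):
        pts = tessellate_sphere(np.zeros(3), 8.0, 1.0)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.min() > 0.75 and nn.max() < 1.25


class TestPlacement:
    def test_united_atom_projection_fixed_point(self):
        mol = united_atom(radius=1.7)
        obs = place_observers(mol, gamma=4.0, spacing=2.0)
        r = np.linalg.norm(obs.points, axis=1)
        assert np.abs(r - 5.7).max() <= 0.05

    @pytest.mark.parametrize("spacing", [2.0, 4.0])
    def test_spacing_modes(self, pyrrolidone, spacing):
        obs = place_observers(pyrrolidone, spacing=spacing)
        base = obs.points[:obs.n_base]
        d = np.linalg.norm(base[:, None] - base[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= spacing

    def test_surface_distance_converged(self, pyrrolidone, obs_pyrrolidone):
        sd = _surface_distances(obs_pyrrolidone.points, pyrrolidone.coords,
                                pyrrolidone.radii)
        assert np.abs(sd - 4.0).max() <= 0.05

    def test_joint_far_ligands_both_sampled(self):
        a = united_atom(pos=(0.0, 0.0, 0.0))
        b = united_atom(pos=(30.0, 0.0, 0.0))
        obs = place_observers([a, b], spacing=2.0)
        for mol in (a, b):
            sd = _surface_distances(obs.points, mol.coords, mol.radii)
            assert sd.min() <= 4.5

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            place_observers([])


class TestStericDistance:
    def test_lone_atom_arithmetic(self):
        mol = united_atom(radius=1.7)
        assert steric_distance(mol, [5.7, 0, 0]) == pytest.approx(4.0)
        assert steric_distance(mol, [1.7, 0, 0]) == pytest.approx(0.0)

    def test_min_rule_matches_brute_force(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 3, (8, 3))
        radii = rng.uniform(1.2, 1.9, 8)
        mol = Molecule(name="m", elements=["C"] * 8, coords=coords,
                       radii=radii)
        for _ in range(20):
            p = rng.normal(0, 6, 3)
            brute = min(np.linalg.norm(p - coords[j]) - radii[j]
                        for j in range(8))
            assert steric_distance(mol, p) == pytest.approx(brute)


class TestCoulombicFeature:
    def test_zero_charges(self):
        mol = united_atom(charge=0.0)
        assert coulombic_energy(mol, [3.0, 0, 0]) == 0.0

    def test_hand_evaluated_close_contact(self):
        # q=+0.5 at 2.0 A with gamma=4: rescaled distance clips to zero,
        # dielectric ~1.00034 -> ~663.9 kcal/mol
        mol = united_atom(charge=0.5)
        v = coulombic_energy(mol, [2.0, 0, 0], gamma=4.0)
        expected = 0.2 * 332.0716 * 0.5 / ((1 + np.exp(-8.0)) * 0.05)
        assert v == pytest.approx(expected, rel=1e-9)
        assert v == pytest.approx(663.9, abs=0.1)

    def test_unbounded_dielectric_kills_far_field(self):
        mol = united_atom(charge=1.0)
        assert abs(coulombic_energy(mol, [30.0, 0, 0])) < 1e-6

    def test_linear_in_charges(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(0, 2, (5, 3))
        q = rng.normal(0, 0.4, 5)
        p = np.array([4.0, 1.0, -2.0])
        m1 = Molecule(name="a", elements=["C"] * 5, coords=coords,
                      charges=q, radii=np.full(5, 1.7))
        m2 = Molecule(name="b", elements=["C"] * 5, coords=coords,
                      charges=2 * q, radii=np.full(5, 1.7))
        assert coulombic_energy(m2, p) == pytest.approx(
            2 * coulombic_energy(m1, p), rel=1e-12)


class TestDonorAcceptorFeatures:
    def test_collinear_donor_angle_is_pi(self):
        # base at origin, proton at +x, observer beyond the proton
        mol = prepare(Molecule(
            name="hf", elements=["N", "H", "H", "H"],
            coords=np.array([[0.0, 0, 0], [1.0, 0, 0],
                             [-0.5, 0.8, 0], [-0.5, -0.8, 0]]),
            bonds=[(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]), "keep")
        dist, theta = donor_feature(mol, [5.0, 0.0, 0.0])
        assert theta == pytest.approx(np.pi)
        assert dist == pytest.approx(4.0 - 1.2)

    def test_pyridine_nitrogen_aimed_at_observer(self, panel):
        mol = panel["pyridine"]
        acc = mol.acceptors[0]
        direction = -acc.direction(mol.coords)  # lone-pair side
        point = mol.coords[acc.index] + 6.0 * direction
        dist, theta = acceptor_feature(mol, point)
        assert theta == pytest.approx(np.pi, abs=1e-6)

    def test_nearest_donor_selected(self):
        rng = np.random.default_rng(4)
        mol = prepare(Molecule(
            name="w", elements=["O", "H", "H"],
            coords=np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]),
            bonds=[(0, 1, 1.0), (0, 2, 1.0)]), "keep")
        for _ in range(20):
            p = rng.normal(0, 5, 3)
            dist, _ = donor_feature(mol, p)
            brute = min(np.linalg.norm(p - mol.coords[d.proton]) - 1.2
                        for d in mol.donors)
            assert dist == pytest.approx(brute)

    def test_absent_features_sentinel(self, panel):
        benz = panel["benzene"]
        dist, theta = donor_feature(benz, [0.0, 0.0, 8.0])
        assert dist > 1e5 and theta == 0.0


class TestComputeFeatures:
    def test_self_consistency_with_target_tables(self, pyrrolidone,
                                                 obs_pyrrolidone):
        table = compute_features(pyrrolidone, obs_pyrrolidone)
        stored = obs_pyrrolidone.tables[0]
        assert np.array_equal(table.as_array(), stored.as_array())

    def test_vectorized_matches_scalar_paths(self, pyrrolidone,
                                             obs_pyrrolidone):
        table = compute_features(pyrrolidone, obs_pyrrolidone)
        for k in range(0, obs_pyrrolidone.n_points, 7):
            p = obs_pyrrolidone.points[k]
            assert table.stc[k] == pytest.approx(
                steric_distance(pyrrolidone, p), abs=1e-9)
            assert table.coul[k] == pytest.approx(
                coulombic_energy(pyrrolidone, p), abs=1e-9)
            d, t = donor_feature(pyrrolidone, p)
            assert table.don[k] == pytest.approx(d, abs=1e-9)
            assert table.don_theta[k] == pytest.approx(t, abs=1e-9)

    def test_rigid_invariance(self, pyrrolidone, obs_pyrrolidone):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -0.8, 0.5]).as_matrix()
        t = np.array([3.0, -1.0, 7.0])
        moved = pyrrolidone.transformed(rot, t)
        obs2_points = obs_pyrrolidone.points @ rot.T + t
        obs2 = type(obs_pyrrolidone)(points=obs2_points, gamma=4.0,
                                     spacing=2.0, targets=[moved])
        a = compute_features(pyrrolidone, obs_pyrrolidone).as_array()
        b = compute_features(moved, obs2).as_array()
        assert np.abs(a - b).max() < 1e-9

    def test_distant_subject_large_steric(self, pyrrolidone,
                                          obs_pyrrolidone):
        far = pyrrolidone.transformed(np.eye(3), np.array([100.0, 0, 0]))
        table = compute_features(far, obs_pyrrolidone)
        assert table.stc.min() > 80
        from esim.kernel import observer_weight

        assert observer_weight(table.stc, 4.0).max() < 1e-9
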