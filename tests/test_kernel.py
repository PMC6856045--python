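"""The similarity kernel: Gaussians, weights, normalization, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esim.kernel import (gauss, normalize_constant, observer_weight,
                         point_similarity, score_pose, sigm,
                         similarity_sticks)
from esim.observers import ObserverSet, compute_features, place_observers
from esim.params import SimParams


class TestScalarKernels:
    def test_gauss_values(self):
        assert gauss(0.0, 2.0) == 1.0
        assert gauss(np.sqrt(2.0), 2.0) == pytest.approx(np.exp(-1))

    @given(st.floats(-50, 50), st.floats(0.1, 10))
    @settings(deadline=None)
    def test_gauss_symmetric_bounded(self, x, sigma):
        assert gauss(-x, sigma) == gauss(x, sigma)
        assert 0.0 <= gauss(x, sigma) <= 1.0

    def test_sigm_values(self):
        assert sigm(0.0, 1.0) == 0.5
        assert sigm(10.0, 0.25) > 1 - 1e-15
        assert sigm(-1e6, 0.25) == 0.0  # overflow-safe

    @given(st.floats(-30, 30), st.floats(0.05, 5))
    @settings(deadline=None)
    def test_sigm_complement(self, x, alpha):
        assert sigm(x, alpha) + sigm(-x, alpha) == pytest.approx(1.0)

    def test_observer_weight(self):
        assert observer_weight(4.0, 4.0) == 1.0
        assert observer_weight(6.0, 4.0) == pytest.approx(np.exp(-2))
        assert observer_weight(2.0, 4.0) == pytest.approx(np.exp(-2))


class TestPointSimilarity:
    def test_identity_saturates(self, pyrrolidone, obs_pyrrolidone):
        table = compute_features(pyrrolidone, obs_pyrrolidone)
        sims = point_similarity(table, table)
        assert np.allclose(sims[:, 0], 1.0)
        assert np.allclose(sims[:, 1], 1.0)
        # points near the donor see a weight approaching 2
        assert sims[:, 2].max() > 1.9

    def test_coulomb_difference_gaussian(self):
        p = SimParams()
        base = np.zeros(1)
        mk = lambda coul: type("T", (), {  # noqa: E731
            "stc": np.array([4.0]), "coul": np.array([coul]),
            "don": np.array([1e6]), "don_theta": base,
            "acc": np.array([1e6]), "acc_theta": base})()
        sims = point_similarity(mk(8.0), mk(0.0), p)
        assert sims[0, 1] == pytest.approx(np.exp(-8.0))

    def test_remote_donors_attract_no_attention(self):
        base = np.zeros(1)
        mk = lambda d: type("T", (), {  # noqa: E731
            "stc": np.array([4.0]), "coul": base,
            "don": np.array([d]), "don_theta": np.array([np.pi]),
            "acc": np.array([1e6]), "acc_theta": base})()
        sims = point_similarity(mk(14.0), mk(14.0))
        assert sims[0, 2] < 1e-9


class TestNormalization:
    def test_self_comparison_is_ten(self, panel):
        for name in ("2-pyrrolidone", "cyclopentanone", "benzene"):
            mol = panel[name]
            obs = place_observers(mol, spacing=2.0)
            assert score_pose(mol, obs, 0.0).total == pytest.approx(
                10.0, abs=1e-6)

    def test_weight_doubling_leaves_score_invariant(self, pyrrolidone):
        p2 = SimParams().with_weights(2.0, 2.0, 2.0)
        obs1 = place_observers(pyrrolidone, spacing=2.0)
        obs2 = place_observers(pyrrolidone, spacing=2.0, params=p2)
        assert obs2.c_t == pytest.approx(2 * obs1.c_t, rel=1e-9)
        assert score_pose(pyrrolidone, obs2, 0.0, p2).total == pytest.approx(
            score_pose(pyrrolidone, obs1, 0.0).total, abs=1e-9)

    def test_joint_query_of_identical_copies(self, pyrrolidone):
        obs1 = place_observers(pyrrolidone, spacing=2.0)
        obs3 = place_observers([pyrrolidone, pyrrolidone.copy(),
                                pyrrolidone.copy()], spacing=2.0)
        assert obs3.c_t == pytest.approx(obs1.c_t, rel=1e-6)
        assert score_pose(pyrrolidone, obs3, 0.0).total == pytest.approx(
            10.0, abs=1e-6)

    def test_degenerate_target_rejected(self, pyrrolidone,
                                        obs_pyrrolidone):
        obs = ObserverSet(points=obs_pyrrolidone.points, gamma=4.0,
                          spacing=2.0, targets=[pyrrolidone])
        far = pyrrolidone.transformed(np.eye(3), np.array([500.0, 0, 0]))
        obs.tables = [compute_features(far, obs)]
        with pytest.raises(ValueError):
            normalize_constant(obs)


class TestScorePose:
    def test_strain_subtracts(self, pyrrolidone, obs_pyrrolidone):
        assert score_pose(pyrrolidone, obs_pyrrolidone, 10.0).total == \
            pytest.approx(9.5, abs=1e-6)

    def test_distant_subject_scores_nothing(self, pyrrolidone,
                                            obs_pyrrolidone):
        far = pyrrolidone.transformed(np.eye(3), np.array([100.0, 0, 0]))
        assert score_pose(far, obs_pyrrolidone, 0.0).total <= 0.01

    def test_breakdown_bookkeeping(self, panel, obs_pyrrolidone):
        bd = score_pose(panel["cyclopentanone"], obs_pyrrolidone, 2.0)
        total = (bd.steric + bd.coulombic + bd.donor + bd.acceptor) / bd.c_t \
            + bd.strain
        assert bd.total == pytest.approx(total, abs=1e-9)
        sums = bd.per_point.sum(axis=0)
        assert sums == pytest.approx(
            [bd.steric, bd.coulombic, bd.donor, bd.acceptor], abs=1e-9)

    def test_gamma_mismatch_rejected(self, pyrrolidone, obs_pyrrolidone):
        import dataclasses

        bad = dataclasses.replace(SimParams(), gamma=5.0)
        with pytest.raises(ValueError):
            score_pose(pyrrolidone, obs_pyrrolidone, 0.0, bad)

    def test_rigid_invariance_of_score(self, panel, pyrrolidone,
                                       obs_pyrrolidone):
        from scipy.spatial.transform import Rotation

        subject = panel["cyclopentanone"]
        rot = Rotation.from_rotvec([0.4, 0.2, -0.9]).as_matrix()
        t = np.array([-2.0, 5.0, 1.0])
        obs2 = ObserverSet(points=obs_pyrrolidone.points @ rot.T + t,
                           gamma=4.0, spacing=2.0,
                           targets=[pyrrolidone.transformed(rot, t)])
        obs2.tables = [compute_features(obs2.targets[0], obs2)]
        obs2.c_t = normalize_constant(obs2)
        a = score_pose(subject, obs_pyrrolidone, 0.0).total
        b = score_pose(subject.transformed(rot, t), obs2, 0.0).total
        assert a == pytest.approx(b, abs=1e-9)

    def test_component_ablation_removes_component(self, panel, pyrrolidone):
        subject = panel["cyclopentanone"]
        p = SimParams().with_weights(1.0, 1.0, 0.0)
        obs = place_observers(pyrrolidone, spacing=2.0, params=p)
        bd = score_pose(subject, obs, 0.0, p)
        assert bd.donor == 0.0 and bd.acceptor == 0.0
        assert score_pose(pyrrolidone, obs, 0.0, p).total == pytest.approx(
            10.0, abs=1e-6)


class TestSticks:
    def test_export_reproduces_sums(self, panel, obs_pyrrolidone):
        bd = score_pose(panel["pyrrole"], obs_pyrrolidone, 0.0)
        df = similarity_sticks(bd, obs_pyrrolidone)
        assert len(df) == obs_pyrrolidone.n_points
        assert df["steric"].sum() == pytest.approx(bd.steric, abs=1e-9)
        assert df["donor"].sum() == pytest.approx(bd.donor, abs=1e-9)

    def test_apolar_pair_has_no_polar_sticks(self, panel):
        benz = panel["benzene"]
        obs = place_observers(benz, spacing=2.0)
        bd = score_pose(panel["toluene"], obs, 0.0)
        df = similarity_sticks(bd, obs)
        assert np.abs(df["donor"]).max() == 0.0
        assert np.abs(df["acceptor"]).max() == 0.0
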