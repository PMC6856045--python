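"""Pose search: downsampling, triangle seeding, BFGS refinement, alignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from esim.alignment import (MODES, align, downsample_ensemble, optimize_pose,
                            rotatable_bonds, triangle_seeds)
from esim.chem import ConformerEnsemble, randomize_pose
from esim.fixtures import build_ensemble, molecule_from_smiles
from esim.kernel import score_pose
from esim.observers import place_observers
from esim.overlap import symmetry_rmsd

from conftest import single_conf


@pytest.fixture(scope="module")
def butanol():
    return build_ensemble("CCCCO", "butanol", n_conf=12, seed=5)


class TestDownsampling:
    def test_within_cap_unchanged(self, butanol):
        assert downsample_ensemble(butanol, 25) is butanol

    def test_preserves_global_minimum(self, butanol):
        out = downsample_ensemble(butanol, 4)
        assert len(out) == 4
        assert out.energies.min() == 0.0

    def test_identical_conformers_cap_one(self, pyrrolidone):
        ens = ConformerEnsemble(pyrrolidone,
                                [pyrrolidone.coords.copy() for _ in range(5)],
                                np.zeros(5))
        out = downsample_ensemble(ens, 1)
        assert len(out) == 1 and out.energies[0] == 0.0


class TestTriangleSeeds:
    def test_self_match_contains_near_identity(self, pyrrolidone,
                                               obs_pyrrolidone):
        seeds = triangle_seeds(pyrrolidone, obs_pyrrolidone)
        best = np.inf
        for r, t in seeds:
            moved = pyrrolidone.coords @ r.T + t
            best = min(best, float(np.sqrt(np.mean(
                np.sum((moved - pyrrolidone.coords) ** 2, axis=1)))))
        assert best <= 0.5

    def test_axis_fallback_for_site_poor_molecules(self):
        methane = molecule_from_smiles("C", "methane", seed=9)
        obs = place_observers(methane, spacing=4.0)
        seeds = triangle_seeds(methane, obs)
        assert len(seeds) == 4
        for r, _ in seeds:
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_linear_molecule_gets_forward_and_flipped_seeds(self):
        lin = molecule_from_smiles("C#N", "hcn", seed=3)
        obs = place_observers(lin, spacing=4.0)
        seeds = triangle_seeds(lin, obs)
        assert len(seeds) >= 2
        # at least one pair of seeds differ by a flip (trace ~ -1 region)
        traces = sorted(np.trace(r) for r, _ in seeds)
        assert traces[0] < traces[-1] - 1.0


class TestOptimizePose:
    def test_stationary_at_self_alignment(self, pyrrolidone,
                                          obs_pyrrolidone):
        coords, tor, score, nit = optimize_pose(
            pyrrolidone, pyrrolidone.coords, obs_pyrrolidone,
            MODES["pscreen"])
        assert score >= 10.0 - 1e-6

    def test_recovers_from_small_jitter(self, pyrrolidone, obs_pyrrolidone):
        rng = np.random.default_rng(2)
        rot = Rotation.from_rotvec(rng.normal(0, 0.05, 3)).as_matrix()
        start = (pyrrolidone.coords - pyrrolidone.coords.mean(0)) @ rot.T \
            + pyrrolidone.coords.mean(0) + rng.normal(0, 0.3, 3)
        _, _, score, _ = optimize_pose(pyrrolidone, start, obs_pyrrolidone,
                                       MODES["pscreen"])
        assert score >= 0.99 * 10.0

    def test_monotone_accept(self, panel, obs_pyrrolidone):
        subject = panel["pyrrole"]
        start = subject.coords + np.array([3.0, 1.0, -2.0])
        s0 = score_pose(subject.with_coords(start), obs_pyrrolidone, 0.0).total
        _, _, score, _ = optimize_pose(subject, start, obs_pyrrolidone,
                                       MODES["pfast"])
        assert score >= s0 - 1e-9


class TestRotatableBonds:
    def test_butanol_chain(self, butanol):
        tds = rotatable_bonds(butanol.molecule)
        assert len(tds) == 2  # C-C-C-C-O backbone; terminal bonds excluded

    def test_amide_excluded(self):
        nmp = molecule_from_smiles("CNC(C)=O", "nma", seed=4)
        tds = rotatable_bonds(nmp)
        els = nmp.elements
        for td in tds:
            assert not ({els[td.i], els[td.j]} == {"C", "N"}
                        and any(o == 2.0 and a in (td.i, td.j)
                                for a, b, o in nmp.bonds))


class TestAlign:
    def test_rigid_self_alignment_recovery(self, pyrrolidone,
                                           obs_pyrrolidone):
        ens = randomize_pose(single_conf(pyrrolidone), seed=21)
        poses = align(ens, obs_pyrrolidone, mode="pscreen", top_n=20)
        best = min(symmetry_rmsd(pyrrolidone.with_coords(p.coords),
                                 pyrrolidone) for p in poses)
        assert best <= 0.5

    def test_determinism(self, pyrrolidone, obs_pyrrolidone):
        ens = randomize_pose(single_conf(pyrrolidone), seed=8)
        a = align(ens, obs_pyrrolidone, mode="pfast", top_n=5)
        b = align(ens, obs_pyrrolidone, mode="pfast", top_n=5)
        assert [p.score for p in a] == [p.score for p in b]
        assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))

    def test_top_one_is_prefix_of_top_twenty(self, pyrrolidone,
                                             obs_pyrrolidone):
        ens = randomize_pose(single_conf(pyrrolidone), seed=13)
        top20 = align(ens, obs_pyrrolidone, mode="pfast", top_n=20)
        top1 = align(ens, obs_pyrrolidone, mode="pfast", top_n=1)
        assert top1[0].score == top20[0].score

    def test_invariant_under_subject_pretransform(self, pyrrolidone,
                                                  obs_pyrrolidone):
        ens1 = randomize_pose(single_conf(pyrrolidone), seed=31)
        ens2 = randomize_pose(ens1, seed=77)
        s1 = align(ens1, obs_pyrrolidone, mode="pscreen", top_n=1)[0].score
        s2 = align(ens2, obs_pyrrolidone, mode="pscreen", top_n=1)[0].score
        assert s1 == pytest.approx(s2, abs=1e-3)

    def test_mode_ordering_on_flexible_self_alignment(self, butanol):
        # deeper search modes never do worse on the same observer frame
        target = butanol.molecule_at(0)
        obs = place_observers(target, spacing=2.0)
        ens = randomize_pose(butanol, seed=3)
        scores = {mode: align(ens, obs, mode=mode, top_n=1)[0].score
                  for mode in ("pfast", "pscreen", "pgeom")}
        assert scores["pgeom"] >= scores["pscreen"] - 1e-6
        assert scores["pscreen"] >= scores["pfast"] - 1e-6
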