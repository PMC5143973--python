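"""Superposition, RMSD/RMSF, hydrogen-bond detection."""

import numpy as np
import pytest

from catpi.ensembles import (
    detect_hbonds,
    kabsch_superpose,
    rmsd_series,
    rmsf_profile,
)
from catpi.structures import Atom, Ensemble, Residue, StructureFrame

from conftest import random_rotation, transform_frame


def _ca_frame(ca_positions, idx=0):
    residues = [
        Residue("A", i + 1, "ALA", atoms=[Atom(i + 1, "CA", "C", np.asarray(p, float))])
        for i, p in enumerate(ca_positions)
    ]
    return StructureFrame(residues=residues, frame_index=idx)


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).standard_normal((8, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(1).standard_normal((8, 3))
        sup = kabsch_superpose(pts, pts + [5.0, 0.0, 0.0])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.translation, [5.0, 0.0, 0.0], atol=1e-9)

    def test_proper_rotation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.standard_normal((6, 3))
            b = rng.standard_normal((6, 3))
            sup = kabsch_superpose(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_optimality_monte_carlo(self):
        # no random rigid transform beats the Kabsch solution
        rng = np.random.default_rng(3)
        mobile = rng.standard_normal((10, 3))
        reference = rng.standard_normal((10, 3))
        best = kabsch_superpose(mobile, reference).rmsd
        for _ in range(1000):
            R = random_rotation(rng)
            t = rng.uniform(-3, 3, 3)
            rmsd = np.sqrt(((mobile @ R.T + t - reference) ** 2).sum(1).mean())
            assert rmsd >= best - 1e-9

    def test_count_mismatch_and_degenerate(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_identical_frames_zero(self):
        f = _ca_frame(np.random.default_rng(4).standard_normal((6, 3)))
        ens = Ensemble(frames=[f, f.copy(), f.copy()])
        np.testing.assert_allclose(rmsd_series(ens), 0.0, atol=1e-9)

    def test_rigid_rotation_removed(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((6, 3))
        f0 = _ca_frame(pts, 0)
        R = random_rotation(rng)
        f1 = transform_frame(f0, R, np.array([3.0, -2.0, 1.0]))
        ens = Ensemble(frames=[f0, f1])
        assert rmsd_series(ens)[1] == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_perturbation(self):
        # move one of N atoms by delta: rmsd <= sqrt(delta^2 / N) after
        # superposition, equality without superposition
        pts = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [4, 4, 0], [4, 0, 4]])
        moved = pts.copy()
        delta = 0.3
        moved[0, 0] += delta
        raw = np.sqrt(((moved - pts) ** 2).sum(1).mean())
        assert raw == pytest.approx(np.sqrt(delta**2 / len(pts)), abs=1e-12)
        ens = Ensemble(frames=[_ca_frame(pts, 0), _ca_frame(moved, 1)])
        assert rmsd_series(ens)[1] <= raw + 1e-12
        assert rmsd_series(ens)[1] == pytest.approx(raw, rel=0.2)


class TestRmsf:
    def test_static_ensemble_zero(self):
        f = _ca_frame(np.random.default_rng(6).standard_normal((5, 3)))
        prof = rmsf_profile(Ensemble(frames=[f, f.copy(), f.copy()]))
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_two_frame_closed_form(self):
        # for 2 frames, rmsf_i = half the inter-frame distance of atom i;
        # exact up to the small share of motion the superposition absorbs,
        # so a large static anchor set keeps the alignment near identity
        rng = np.random.default_rng(10)
        pts = rng.uniform(-12, 12, (60, 3))
        moved = pts.copy()
        moved[2] += [0.0, 0.0, 0.8]
        ens = Ensemble(frames=[_ca_frame(pts, 0), _ca_frame(moved, 1)])
        prof = rmsf_profile(ens)
        assert prof.rmsf[2] == pytest.approx(0.4, abs=0.02)
        assert prof.rmsf.argmax() == 2

    def test_oscillating_residue_amplitude(self):
        # residue 3 oscillates +/- a along x in alternate frames; with a
        # large static anchor set the rest of the profile stays near zero
        rng = np.random.default_rng(7)
        anchor = rng.uniform(-10, 10, (100, 3))
        a = 0.5
        frames = []
        for i in range(10):
            pts = anchor.copy()
            pts[3, 0] += a if i % 2 == 0 else -a
            frames.append(_ca_frame(pts, i))
        prof = rmsf_profile(Ensemble(frames=frames))
        assert prof.rmsf[3] == pytest.approx(a, abs=0.02)
        others = np.delete(prof.rmsf, 3)
        assert others.max() < 0.05

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        frames = [_ca_frame(rng.standard_normal((7, 3)), i) for i in range(5)]
        base = rmsf_profile(Ensemble(frames=frames)).rmsf
        moved = [
            transform_frame(f, random_rotation(rng), rng.uniform(-9, 9, 3))
            for f in frames
        ]
        got = rmsf_profile(Ensemble(frames=moved)).rmsf
        np.testing.assert_allclose(got, base, atol=1e-6)

    def test_damped_loop_contrast(self):
        # "mutant" ensemble with damped loop motion shows lower loop RMSF
        rng = np.random.default_rng(9)
        anchor = rng.uniform(-10, 10, (30, 3))
        loop = slice(10, 18)

        def build(amplitude, seed):
            r = np.random.default_rng(seed)
            frames = []
            for i in range(12):
                pts = anchor.copy()
                pts[loop] += amplitude * r.standard_normal(pts[loop].shape)
                frames.append(_ca_frame(pts, i))
            return Ensemble(frames=frames)

        wt = rmsf_profile(build(1.0, 1))
        mut = rmsf_profile(build(0.3, 2))
        assert mut.rmsf[loop].mean() < wt.rmsf[loop].mean()

    def test_single_frame_rejected(self):
        f = _ca_frame(np.zeros((5, 3)) + np.arange(5)[:, None])
        with pytest.raises(ValueError):
            rmsf_profile(Ensemble(frames=[f]))


def _nh_res(num, pos_n, pos_h=None, chain="A"):
    atoms = [Atom(1, "N", "N", np.asarray(pos_n, float))]
    if pos_h is not None:
        atoms.append(Atom(2, "H", "H", np.asarray(pos_h, float)))
    return Residue(chain, num, "ALA", atoms=atoms)


def _o_res(num, pos, chain="A"):
    return Residue(chain, num, "ALA", atoms=[Atom(1, "O", "O", np.asarray(pos, float))])


class TestHbonds:
    def test_heavy_atom_mode(self):
        f = StructureFrame(residues=[_nh_res(1, [0, 0, 0]), _o_res(3, [2.9, 0, 0])])
        recs = detect_hbonds(Ensemble(frames=[f]))
        assert len(recs) == 1
        assert recs[0].mean_distance == pytest.approx(2.9)
        assert recs[0].occupancy_pct == 100.0
        assert recs[0].mean_angle is None

    def test_distance_boundary(self):
        f = StructureFrame(residues=[_nh_res(1, [0, 0, 0]), _o_res(3, [3.6, 0, 0])])
        assert detect_hbonds(Ensemble(frames=[f])) == []

    def test_angle_rule_with_hydrogens(self):
        # linear N-H...O passes; orthogonal H fails
        good = StructureFrame(
            residues=[_nh_res(1, [0, 0, 0], [1.0, 0, 0]), _o_res(3, [2.9, 0, 0])]
        )
        recs = detect_hbonds(Ensemble(frames=[good]))
        assert any(r.mean_angle == pytest.approx(180.0, abs=1e-6) for r in recs)
        bad = StructureFrame(
            residues=[_nh_res(1, [0, 0, 0], [0.0, 1.0, 0]), _o_res(3, [2.9, 0, 0])]
        )
        # donor->acceptor direction fails the angle; acceptor has no H so
        # the reverse direction never forms
        assert detect_hbonds(Ensemble(frames=[bad])) == []

    def test_occupancy_over_frames(self):
        near = StructureFrame(residues=[_nh_res(1, [0, 0, 0]), _o_res(3, [2.9, 0, 0])])
        far = StructureFrame(residues=[_nh_res(1, [0, 0, 0]), _o_res(3, [6.9, 0, 0])])
        recs = detect_hbonds(Ensemble(frames=[near, far.copy(), near.copy(), far.copy()]))
        assert len(recs) == 1
        assert recs[0].occupancy_pct == pytest.approx(50.0)

    def test_matches_brute_force_all_pairs(self, scaffold30):
        recs = detect_hbonds(Ensemble(frames=[scaffold30]), d_cut=3.5)
        got = {frozenset((r.donor, r.acceptor)) for r in recs}
        expected = set()
        for ri in scaffold30:
            for rj in scaffold30:
                if ri.key >= rj.key:
                    continue
                for ai in ri.atoms:
                    if ai.element not in ("N", "O"):
                        continue
                    for aj in rj.atoms:
                        if aj.element not in ("N", "O"):
                            continue
                        if np.linalg.norm(ai.coords - aj.coords) <= 3.5:
                            expected.add(
                                frozenset(((ri.key, ai.name), (rj.key, aj.name)))
                            )
        assert got == expected
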