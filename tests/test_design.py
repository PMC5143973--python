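"""In-silico mutation design: enumeration, placement, assessment, screening."""

import itertools

import numpy as np
import pytest

from catpi._build import CHI_ATOMS, graft_side_chain, ideal_side_chain_template, set_chi
from catpi.design import (
    DEFAULT_CHI_GRID,
    MutationCandidate,
    assess_candidate,
    enumerate_candidates,
    place_side_chain,
    screen_candidates,
)
from catpi.ensembles import kabsch_superpose
from catpi.geometry import CriteriaConfig, aromatic_rings, cation_group, pair_geometry
from catpi.structures import Atom, Residue, ResidueKey, StructureFrame
from catpi.synth import make_ensemble, make_pair_fixture, make_scaffold


class TestEnumeration:
    def test_thr_near_arg_becomes_tyr_candidate(self, scaffold30):
        cands = enumerate_candidates(scaffold30, proximity_cut=8.0)
        thr = [c for c in cands if c.site == ResidueKey("A", 10)]
        assert len(thr) == 1
        assert thr[0].new_res == "TYR" and thr[0].partner == ResidueKey("A", 8)

    def test_ser_near_trp_becomes_lys_candidate(self, scaffold30):
        cands = enumerate_candidates(scaffold30, proximity_cut=8.0)
        ser = [c for c in cands if c.site == ResidueKey("A", 22)]
        assert len(ser) == 1
        assert ser[0].new_res == "LYS" and ser[0].partner == ResidueKey("A", 20)

    def test_exclusions_suppress_candidates(self, scaffold30):
        cands = enumerate_candidates(
            scaffold30, 8.0, exclusions={ResidueKey("A", 10)}
        )
        assert not any(c.site == ResidueKey("A", 10) for c in cands)

    def test_matches_brute_force_double_loop(self, scaffold30):
        cut = 8.0
        cands = enumerate_candidates(scaffold30, cut)
        got = {(c.site, c.new_res, c.partner) for c in cands}
        # independent brute-force oracle over all residue pairs
        expected = {}
        for t in scaffold30:
            if t.res_name not in ("LYS", "ARG", "PHE", "TYR", "TRP"):
                continue
            new_res = "TYR" if t.res_name in ("LYS", "ARG") else "LYS"
            ta = t.atom("CB") or (t.atom("CA") if t.res_name == "GLY" else None)
            for s in scaffold30:
                if s.key == t.key or s.res_name == new_res:
                    continue
                sa = s.atom("CB") or (s.atom("CA") if s.res_name == "GLY" else None)
                if sa is None or ta is None:
                    continue
                d = np.linalg.norm(sa.coords - ta.coords)
                if d <= cut:
                    key = (s.key, new_res)
                    if key not in expected or d < expected[key][1]:
                        expected[key] = (t.key, d)
        assert got == {(site, nr, tk) for (site, nr), (tk, _) in expected.items()}

    def test_order_invariance(self, scaffold30):
        shuffled = StructureFrame(residues=list(reversed(scaffold30.residues)))
        a = enumerate_candidates(scaffold30, 8.0)
        b = enumerate_candidates(shuffled, 8.0)
        assert {(c.site, c.new_res, c.partner) for c in a} == {
            (c.site, c.new_res, c.partner) for c in b
        }

    def test_nonpositive_cut_rejected(self, scaffold30):
        with pytest.raises(ValueError):
            enumerate_candidates(scaffold30, 0.0)


class TestPlacement:
    def test_rotamer_count_is_grid_power(self, scaffold30):
        tyr = place_side_chain(scaffold30, "A:15", "TYR")
        assert len(tyr) == len(DEFAULT_CHI_GRID) ** 2
        lys = place_side_chain(scaffold30, "A:15", "LYS")
        assert len(lys) == len(DEFAULT_CHI_GRID) ** 4

    def test_other_residues_untouched(self, scaffold30):
        _, mutated = place_side_chain(scaffold30, "A:15", "TYR")[0]
        for orig, new in zip(scaffold30, mutated):
            if orig.seq_number == 15:
                continue
            np.testing.assert_array_equal(
                orig.coords_of([a.name for a in orig.atoms]),
                new.coords_of([a.name for a in orig.atoms]),
            )

    def test_rebuilt_ring_is_valid_and_ideal(self, scaffold30):
        _, mutated = place_side_chain(scaffold30, "A:15", "TYR")[0]
        tyr = mutated.residue("A:15")
        (ring,) = aromatic_rings(tyr)
        # ring bond lengths within 0.05 A of the aromatic ideal
        order = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        pts = tyr.coords_of(order)
        for i in range(6):
            bond = np.linalg.norm(pts[i] - pts[(i + 1) % 6])
            assert bond == pytest.approx(1.39, abs=0.05)

    def test_gly_site_gets_cbeta(self):
        scaffold = make_scaffold(10, motif_sites={5: "GLY"})
        _, mutated = place_side_chain(scaffold, "A:5", "TYR")[0]
        assert mutated.residue("A:5").atom("CB") is not None

    def test_missing_backbone_raises(self, scaffold30):
        broken = scaffold30.copy()
        res = broken.residue("A:15")
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(ValueError, match="CA"):
            place_side_chain(broken, "A:15", "TYR")


def _face_on_site_fixture(distance=4.5, theta=10.0, chis=(-60.0, 60.0)):
    """Frame where one grid rotamer of a Tyr at the site is exactly
    face-on to a Lys ammonium at the requested geometry."""
    template = ideal_side_chain_template("TYR")
    for quad, v in zip(CHI_ATOMS["TYR"], chis):
        template = set_chi(template, quad, v)
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    ring = np.array([template[n] for n in ring_names])
    centroid = ring.mean(axis=0)
    _, _, vt = np.linalg.svd(ring - centroid)
    normal = vt[-1]
    # rigid transform: centroid -> origin, normal -> +z
    axis_target = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, axis_target)
    s, c = np.linalg.norm(v), float(np.dot(normal, axis_target))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    placed = {n: R @ (xyz - centroid) for n, xyz in template.items()}
    site_atoms = [
        Atom(i + 1, n, ("N" if n == "N" else "O" if n == "O" else "C"), placed[n])
        for i, n in enumerate(("N", "CA", "C", "O"))
    ]
    site = Residue("A", 1, "ALA", atoms=site_atoms)
    th = np.radians(theta)
    nz = distance * np.array([np.sin(th), 0.0, np.cos(th)])
    lys_atoms = [
        Atom(10, "NZ", "N", nz),
        Atom(11, "CE", "C", nz + [0, 0, 1.49]),
        Atom(12, "CD", "C", nz + [0, 1.2, 2.3]),
        Atom(13, "CG", "C", nz + [0, 0, 3.3]),
        Atom(14, "CB", "C", nz + [0, 1.2, 4.2]),
        Atom(15, "CA", "C", nz + [0, 0, 5.2]),
        Atom(16, "N", "N", nz + [0, 1.2, 6.0]),
        Atom(17, "C", "C", nz + [0, -1.0, 5.9]),
    ]
    lys = Residue("A", 5, "LYS", atoms=lys_atoms)
    return StructureFrame(residues=[site, lys])


class TestAssessment:
    def test_face_on_rotamer_is_feasible(self):
        frame = _face_on_site_fixture()
        cand = MutationCandidate(
            site=ResidueKey("A", 1), wild_res="ALA", new_res="TYR",
            partner=ResidueKey("A", 5), partner_res="LYS", cb_distance=6.0,
        )
        out = assess_candidate(frame, cand)
        assert out.feasible
        assert out.clash_count == 0
        assert out.placed_geometry.distance_d <= 6.0
        assert out.placed_geometry.theta_axial <= 60.0

    def test_clash_cage_infeasible(self, lys_tyr_pair):
        # surround the site with a cage of dummy heavy atoms
        frame = lys_tyr_pair.copy()
        site = frame.residue("A:1")
        cage_atoms = []
        k = 0
        for dx, dy, dz in itertools.product((-2.0, 0.0, 2.0), repeat=3):
            k += 1
            cage_atoms.append(
                Atom(100 + k, "O", "O", site.atom("CA").coords + [dx, dy, dz])
            )
        frame.residues.append(Residue("B", 99, "UNK", atoms=cage_atoms))
        cand = MutationCandidate(
            site=ResidueKey("A", 1), wild_res="TYR", new_res="TYR",
            partner=ResidueKey("A", 5), partner_res="LYS", cb_distance=4.0,
        )
        out = assess_candidate(frame, cand)
        assert not out.feasible
        assert out.clash_count > 0

    def test_matches_exhaustive_rotamer_oracle(self):
        frame = _face_on_site_fixture()
        cand = MutationCandidate(
            site=ResidueKey("A", 1), wild_res="ALA", new_res="TYR",
            partner=ResidueKey("A", 5), partner_res="LYS", cb_distance=6.0,
        )
        out = assess_candidate(frame, cand)
        # oracle: enumerate every rotamer directly
        from catpi.design import _count_clashes
        from catpi.geometry import is_cation_pi

        best = None
        for chis, mframe in place_side_chain(frame, "A:1", "TYR"):
            if _count_clashes(mframe, ResidueKey("A", 1), 2.5):
                continue
            cat = cation_group(mframe.residue("A:5"))
            geo = min(
                (pair_geometry(cat, r) for r in aromatic_rings(mframe.residue("A:1"))),
                key=lambda g: g.distance_d,
            )
            if best is None or geo.distance_d < best[0]:
                best = (geo.distance_d, chis, is_cation_pi(geo)[0])
        assert best is not None
        assert out.best_rotamer == best[1]
        assert out.feasible == best[2]


class TestScreening:
    @pytest.mark.parametrize(
        "occupancy,n,expected_pct,passes",
        [(0.5, 10, 50.0, False), (0.6, 10, 60.0, True), (1.0, 7, 100.0, True),
         (0.0, 10, 0.0, False), (0.51, 100, 51.0, True)],
    )
    def test_designed_occupancy_recovered(self, lys_tyr_pair, occupancy, n, expected_pct, passes):
        ens = make_ensemble(lys_tyr_pair, ("A:1", "A:5"), occupancy, n, seed=4)
        cand = MutationCandidate(
            site=ResidueKey("A", 5), wild_res="LYS", new_res="LYS",
            partner=ResidueKey("A", 1), partner_res="TYR", cb_distance=4.0,
        )
        (res,) = screen_candidates(ens, [cand])
        assert res.occupancy_pct == pytest.approx(expected_pct)
        assert res.passes_screen is passes

    def test_occupancy_invariant_to_frame_order_and_duplication(self, lys_tyr_pair):
        from catpi.structures import Ensemble

        ens = make_ensemble(lys_tyr_pair, ("A:1", "A:5"), 0.6, 10, seed=0)
        cand = MutationCandidate(
            site=ResidueKey("A", 5), wild_res="LYS", new_res="LYS",
            partner=ResidueKey("A", 1), partner_res="TYR", cb_distance=4.0,
        )
        base = screen_candidates(ens, [cand])[0].occupancy_pct
        rev = Ensemble(frames=list(reversed(ens.frames)))
        assert screen_candidates(rev, [cand])[0].occupancy_pct == base
        doubled = Ensemble(frames=ens.frames + ens.frames)
        assert screen_candidates(doubled, [cand])[0].occupancy_pct == base
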