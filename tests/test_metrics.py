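import numpy as np
import pytest

import ectofit as ef
from ectofit.metrics import (center_of_mass, contact_map, hinge_angle,
                             hinge_report, kabsch_superpose, rmsd)
from ectofit.structure import DomainDefinition, Selection


def _atoms(positions, elements=None):
    n = len(positions)
    elements = elements or ["C"] * n
    return ef.Structure(
        np.arange(1, n + 1), np.array(["CA"] * n, dtype=object),
        np.array(elements, dtype=object), np.arange(1, n + 1),
        np.array(["ALA"] * n, dtype=object), np.array(["A"] * n, dtype=object),
        np.asarray(positions, dtype=float))


def _rotation(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        st = _atoms([[0, 0, 0], [2, 0, 0]])
        assert np.allclose(center_of_mass(st.select_all()), [1, 0, 0])

    def test_mass_weighting(self):
        st = _atoms([[0, 0, 0], [4, 0, 0]], elements=["C", "O"])
        mC, mO = st.mass
        want = 4 * mO / (mC + mO)
        assert center_of_mass(st.select_all())[0] == pytest.approx(want)

    def test_union_combination(self, rng):
        st = _atoms(rng.normal(size=(20, 3)),
                    elements=list(rng.choice(["C", "N", "O", "S"], size=20)))
        a = Selection(st, np.arange(8))
        b = Selection(st, np.arange(8, 20))
        com_u = center_of_mass(a.union(b))
        # brute-force oracle over atoms
        m = st.mass
        want = (st.xyz * m[:, None]).sum(axis=0) / m.sum()
        assert np.allclose(com_u, want, atol=1e-12)

    def test_empty_raises(self, helix):
        with pytest.raises(ValueError):
            center_of_mass(Selection(helix, np.array([], dtype=np.int64)))


class TestHingeAngle:
    def test_collinear_is_180(self):
        assert hinge_angle([1, 0, 0], [0, 0, 0], [-1, 0, 0]) == pytest.approx(180.0)

    def test_right_angle(self):
        assert hinge_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_near_collinear_stability(self):
        ang = hinge_angle([1, 0, 0], [0, 0, 0], [-1, 1e-8, 0])
        assert ang == pytest.approx(180.0, abs=1e-3)

    def test_zero_arm_raises(self):
        with pytest.raises(ValueError):
            hinge_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_transform_and_scaling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, v, b = rng.normal(size=(3, 3)) * 10
        base = hinge_angle(a, v, b)
        R = _rotation(rng.normal(size=3), rng.uniform(10, 350))
        t = rng.normal(size=3) * 5
        assert hinge_angle(a @ R.T + t, v @ R.T + t, b @ R.T + t) == pytest.approx(base, abs=1e-9)
        s = 3.7
        assert hinge_angle(v + s * (a - v), v, v + s * (b - v)) == pytest.approx(base, abs=1e-9)


class TestHingeReport:
    def test_designed_angles_recovered(self, toy_receptor):
        receptor, gt = toy_receptor
        rep = hinge_report(receptor, gt.domains, gt.hinges)
        for sub, table in gt.hinge_table.items():
            for name, want in table.items():
                assert rep.angles[sub][name] == pytest.approx(want, abs=1e-6)

    def test_dimer_symmetry(self, toy_receptor):
        receptor, gt = toy_receptor
        rep = hinge_report(receptor, gt.domains, gt.hinges)
        assert all(v < 1e-6 for v in rep.asymmetry.values())

    def test_mirror_image_same_angles(self, toy_receptor):
        receptor, gt = toy_receptor
        mirror = receptor.copy()
        mirror.xyz[:, 0] *= -1
        rep = hinge_report(receptor, gt.domains, gt.hinges)
        rep_m = hinge_report(mirror, gt.domains, gt.hinges)
        for sub in rep.angles:
            for h in rep.angles[sub]:
                assert rep_m.angles[sub][h] == pytest.approx(rep.angles[sub][h], abs=1e-9)

    def test_deltas_sign_convention(self, toy_receptor):
        receptor, gt = toy_receptor
        deltas = {"F1-F2": -9.0, "F2-F3": -13.0, "L1-L2": -7.0, "L2-F1": 6.0}
        start, target, _ = ef.make_deformed_pair(receptor, deltas, gt, subunits=["A"])
        rep = hinge_report(target, gt.domains, gt.hinges, reference=start)
        for name, want in deltas.items():
            assert rep.deltas["A"][name] == pytest.approx(want, abs=1e-6)
            assert rep.deltas["B"][name] == pytest.approx(0.0, abs=1e-6)

    def test_missing_domain_named_in_error(self, toy_receptor):
        receptor, gt = toy_receptor
        doms = [d for d in gt.domains if d.name != "F2"]
        with pytest.raises(ValueError, match="F2"):
            hinge_report(receptor, doms, gt.hinges)


class TestKabsch:
    def test_self_alignment(self, helix):
        R, t, r = kabsch_superpose(helix.select_all(), helix.select_all())
        assert r == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_constructed_rotation(self, seed, helix):
        rng = np.random.default_rng(seed)
        R0 = _rotation(rng.normal(size=3), rng.uniform(5, 170))
        t0 = rng.normal(size=3) * 8
        moved = helix.xyz @ R0.T + t0
        R, t, r = kabsch_superpose(moved, helix.xyz)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, R0.T, atol=1e-9)

    def test_collinear_input_raises(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(pts, pts)

    def test_no_reflection(self, helix, rng):
        mirrored = helix.xyz.copy()
        mirrored[:, 0] *= -1
        R, _, _ = kabsch_superpose(mirrored, helix.xyz)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_superposed_rmsd_never_exceeds_direct(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(30, 3)) * 5
        b = a @ _rotation(rng.normal(size=3), 25).T + rng.normal(size=3)
        b += rng.normal(scale=0.4, size=b.shape)
        assert rmsd(a, b, superpose=True) <= rmsd(a, b) + 1e-12

    def test_agrees_with_scipy(self, rng):
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(25, 3)) * 4
        b = a @ _rotation([1, 2, 3], 40).T + np.array([1.0, -2.0, 0.5])
        b += rng.normal(scale=0.2, size=b.shape)
        R, t, r = kabsch_superpose(a, b)
        rot, ssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert np.allclose(R, rot.as_matrix(), atol=1e-8)


class TestContacts:
    def test_far_residues_empty(self):
        a = _atoms([[0, 0, 0]])
        b = _atoms([[20, 0, 0]])
        st = ef.concatenate([a, b], chain_map={1: "B"})
        recs = contact_map(st.select_chain("A"), st.select_chain("B"), cutoff=5.0)
        assert recs == []

    def test_exact_cutoff_included(self):
        a = _atoms([[0, 0, 0]])
        b = _atoms([[5.0, 0, 0]])
        st = ef.concatenate([a, b], chain_map={1: "B"})
        recs = contact_map(st.select_chain("A"), st.select_chain("B"), cutoff=5.0)
        assert len(recs) == 1
        assert recs[0].min_distance == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        a = _atoms(rng.normal(size=(40, 3)) * 6)
        b = _atoms(rng.normal(size=(40, 3)) * 6 + np.array([4.0, 0, 0]))
        st = ef.concatenate([a, b], chain_map={1: "B"})
        sa, sb = st.select_chain("A"), st.select_chain("B")
        recs = contact_map(sa, sb, cutoff=5.0)
        got = {(r.residue_a, r.residue_b): r.min_distance for r in recs}
        # O(N^2) oracle over residue pairs
        want = {}
        for i in sa.indices:
            for j in sb.indices:
                d = float(np.linalg.norm(st.xyz[i] - st.xyz[j]))
                if d <= 5.0:
                    ka = (st.chain[i], int(st.resseq[i]))
                    kb = (st.chain[j], int(st.resseq[j]))
                    want[(ka, kb)] = min(want.get((ka, kb), np.inf), d)
        assert got.keys() == want.keys()
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)

    def test_transpose_symmetry(self, rng):
        a = _atoms(rng.normal(size=(25, 3)) * 5)
        b = _atoms(rng.normal(size=(25, 3)) * 5 + 3.0)
        st = ef.concatenate([a, b], chain_map={1: "B"})
        ab = contact_map(st.select_chain("A"), st.select_chain("B"))
        ba = contact_map(st.select_chain("B"), st.select_chain("A"))
        assert {(r.residue_a, r.residue_b, round(r.min_distance, 9)) for r in ab} \
            == {(r.residue_b, r.residue_a, round(r.min_distance, 9)) for r in ba}

    def test_overlapping_selections_rejected(self, helix):
        with pytest.raises(ValueError):
            contact_map(helix.select_all(), helix.select_all())
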