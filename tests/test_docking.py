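import numpy as np
import pytest

import ectofit as ef
from ectofit.docking import (RigidPose, clash_score, clash_score_points,
                             map_overlap, mc_dock, metropolis_accept,
                             screen_ensemble, select_low_energy)
from ectofit.fitting import build_map_potential
from ectofit.metrics import center_of_mass
from ectofit.structure import Selection


def _cloud(rng, n=50, scale=8.0, offset=0.0):
    return rng.normal(size=(n, 3)) * scale + offset


class TestClashScore:
    def test_far_pair(self):
        c, e = clash_score_points(np.array([[0.0, 0, 0]]), np.array([[10.0, 0, 0]]), 2.5)
        assert (c, e) == (0, 0.0)

    def test_coincident_pair_energy(self):
        c, e = clash_score_points(np.array([[1.0, 2, 3]]), np.array([[1.0, 2, 3]]), 2.5)
        assert c == 1
        assert e == pytest.approx(2.5**2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pa = _cloud(rng)
        pb = _cloud(rng, offset=rng.uniform(-4, 4, size=3))
        count, energy = clash_score_points(pa, pb, 2.5)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        close = d < 2.5
        assert count == int(close.sum())
        assert energy == pytest.approx(float(np.sum((d[close] - 2.5) ** 2)), abs=1e-9)

    def test_symmetry(self, rng):
        pa, pb = _cloud(rng), _cloud(rng)
        assert clash_score_points(pa, pb) == clash_score_points(pb, pa)

    def test_overlapping_selections_rejected(self, helix):
        with pytest.raises(ValueError):
            clash_score(helix.select_all(), helix.select_all())


class TestMapOverlap:
    def test_self_overlap_near_one(self, bundle):
        g = ef.synthesize_map(bundle.select_all(), 4.0, 1.0)
        assert map_overlap(bundle.select_all(), g) > 0.95

    def test_displaced_far_is_zero(self, bundle):
        g = ef.synthesize_map(bundle.select_all(), 4.0, 1.0)
        moved = bundle.copy()
        moved.xyz += 500.0
        assert map_overlap(moved.select_all(), g) == 0.0

    def test_constructed_half_membership(self, bundle):
        g = ef.synthesize_map(bundle.select_all(), 4.0, 1.0)
        inside = bundle.xyz[:20].copy()
        outside = bundle.xyz[:20] + 500.0
        st = ef.Structure(
            np.arange(1, 41), np.array(["CA"] * 40, dtype=object),
            np.array(["C"] * 40, dtype=object), np.arange(1, 41),
            np.array(["ALA"] * 40, dtype=object), np.array(["A"] * 40, dtype=object),
            np.vstack([inside, outside]))
        ov = map_overlap(st.select_all(), g)
        assert ov == pytest.approx(0.5, abs=1.0 / 40)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert metropolis_accept(-1.0, 1.0, rng)
        assert metropolis_accept(0.0, 1.0, rng)

    def test_two_state_occupancy_ratio(self):
        # two-state landscape with dE = 1.2, T = 1.0: empirical occupancy
        # ratio must match exp(-dE/T) within 3 standard errors
        rng = np.random.default_rng(7)
        dE, T = 1.2, 1.0
        state = 0
        counts = np.zeros(2, dtype=int)
        n = 100_000
        for _ in range(n):
            new = 1 - state
            delta = dE if new == 1 else -dE
            if metropolis_accept(delta, T, rng):
                state = new
            counts[state] += 1
        ratio = counts[1] / counts[0]
        want = np.exp(-dE / T)
        p1 = want / (1 + want)
        se = np.sqrt(p1 * (1 - p1) / n)
        # propagate the SE of p1 to the ratio p1/(1-p1)
        se_ratio = se / (1 - p1) ** 2
        assert abs(ratio - want) < 3 * se_ratio


class TestMcDock:
    def test_same_seed_bitwise_identical(self, docking_toy):
        toy = docking_toy
        lig = Selection(toy.cplx, toy.cplx.annotations["ligand"], "lig")
        rec = Selection(toy.cplx, toy.cplx.annotations["receptor"], "rec")
        mp = build_map_potential(toy.ligand_map, xi=1.0)
        r1 = mc_dock(lig, rec, [mp], n_steps=300, seed=42)
        r2 = mc_dock(lig, rec, [mp], n_steps=300, seed=42)
        assert len(r1.accepted) == len(r2.accepted)
        for p, q in zip(r1.accepted, r2.accepted):
            assert np.array_equal(p.rotation, q.rotation)
            assert np.array_equal(p.translation, q.translation)

    def test_infinite_temperature_accepts_everything(self, docking_toy):
        toy = docking_toy
        lig = Selection(toy.cplx, toy.cplx.annotations["ligand"], "lig")
        rec = Selection(toy.cplx, toy.cplx.annotations["receptor"], "rec")
        mp = build_map_potential(toy.ligand_map, xi=1.0)
        res = mc_dock(lig, rec, [mp], temperature=1e12, n_steps=2000, seed=3)
        assert res.acceptance_rate > 0.98

    def test_near_zero_temperature_converges_to_planted_pose(self, docking_toy):
        toy = docking_toy
        lig = Selection(toy.cplx, toy.cplx.annotations["ligand"], "lig")
        rec = Selection(toy.cplx, toy.cplx.annotations["receptor"], "rec")
        mp = build_map_potential(toy.ligand_map, xi=1.0)
        res = mc_dock(lig, rec, [mp], moveset=(1.0, 6.0), temperature=1e-4,
                      n_steps=1500, seed=11, w_map=20.0)
        best = res.best.apply(lig.positions, center_of_mass(lig))
        assert ef.rmsd(best, toy.planted_ligand_xyz) < 1.0

    def test_best_pose_is_lowest_energy(self, docking_toy):
        toy = docking_toy
        lig = Selection(toy.cplx, toy.cplx.annotations["ligand"], "lig")
        mp = build_map_potential(toy.ligand_map, xi=1.0)
        res = mc_dock(lig, None, [mp], n_steps=500, seed=5)
        assert res.best.total <= min(p.total for p in res.accepted)

    def test_invalid_args(self, docking_toy):
        lig = Selection(docking_toy.cplx, docking_toy.cplx.annotations["ligand"])
        with pytest.raises(ValueError):
            mc_dock(lig, None, [], n_steps=0)
        with pytest.raises(ValueError):
            mc_dock(lig, None, [], moveset=(0.0, 5.0))


class TestPoseValidation:
    def test_rotation_must_be_proper(self):
        bad = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidPose(bad, np.zeros(3))

    def test_rotation_must_be_orthonormal(self):
        with pytest.raises(ValueError):
            RigidPose(np.eye(3) * 1.1, np.zeros(3))


@pytest.fixture(scope="module")
def ensemble(docking_toy):
    """49 decoys pushed into the ligand density + the planted clash-free
    receptor conformation."""
    toy = docking_toy
    rng = np.random.default_rng(0)
    rec_idx = toy.cplx.annotations["receptor"]
    lig_com = toy.planted_ligand_xyz.mean(axis=0)
    confs, ids = [], []
    base = toy.cplx.subset(rec_idx)
    confs.append(base.copy())
    ids.append("planted")
    rec_com = base.xyz.mean(axis=0)
    toward = (lig_com - rec_com) / np.linalg.norm(lig_com - rec_com)
    for k in range(49):
        decoy = base.copy()
        decoy.xyz += toward * rng.uniform(12.0, 25.0) \
            + rng.normal(scale=1.0, size=3)
        confs.append(decoy)
        ids.append(f"decoy{k:02d}")
    for c in confs:
        c.add_annotation("arm", np.arange(c.n_atoms))
    return confs, ids


class TestScreening:

    def test_only_planted_conformation_passes_zero_tolerance(self, docking_toy, ensemble):
        confs, ids = ensemble
        records = screen_ensemble(confs, docking_toy.ligand_map, "arm",
                                  overlap_tol=0.0, clash_tol=0, ids=ids)
        passed = [r for r in records if r.passed]
        assert [r.conformation_id for r in passed] == ["planted"]
        assert records[0].conformation_id == "planted"

    def test_degenerate_ensemble_identical_records(self, docking_toy):
        base = docking_toy.cplx.subset(docking_toy.cplx.annotations["receptor"])
        base.add_annotation("arm", np.arange(base.n_atoms))
        confs = [base.copy() for _ in range(4)]
        for c in confs:
            c.add_annotation("arm", np.arange(c.n_atoms))
        records = screen_ensemble(confs, docking_toy.ligand_map, "arm")
        assert len({(r.overlap, r.clash_count, r.passed) for r in records}) == 1

    def test_tolerance_monotonicity(self, docking_toy, ensemble):
        confs, ids = ensemble
        tight = screen_ensemble(confs, docking_toy.ligand_map, "arm",
                                overlap_tol=0.0, ids=ids)
        loose = screen_ensemble(confs, docking_toy.ligand_map, "arm",
                                overlap_tol=0.3, ids=ids)
        tight_pass = {r.conformation_id for r in tight if r.passed}
        loose_pass = {r.conformation_id for r in loose if r.passed}
        assert tight_pass <= loose_pass

    def test_empty_ensemble_raises(self, docking_toy):
        with pytest.raises(ValueError):
            screen_ensemble([], docking_toy.ligand_map, "arm")


class TestSelectLowEnergy:
    def test_clash_free_ranks_first(self, docking_toy):
        toy = docking_toy
        rec = Selection(toy.cplx, toy.cplx.annotations["receptor"], "rec")
        lig = toy.cplx.subset(toy.cplx.annotations["ligand"])
        clashing = lig.copy()
        clashing.xyz = toy.cplx.xyz[rec.indices[:lig.n_atoms]] + 0.5
        ranked = select_low_energy([clashing, lig], rec)
        assert ranked[0][0] == 1
        assert ranked[0][1] < ranked[1][1]

    def test_rigid_motion_invariance(self, docking_toy, rng):
        toy = docking_toy
        cplx = toy.cplx.copy()
        rec = Selection(cplx, cplx.annotations["receptor"], "rec")
        lig = cplx.subset(cplx.annotations["ligand"])
        base = select_low_energy([lig], rec)[0][1]
        # same rigid transform applied to candidate and context jointly
        axis = rng.normal(size=3); axis /= np.linalg.norm(axis)
        ang = np.radians(73.0)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        t = np.array([3.0, -7.0, 11.0])
        cplx.xyz = cplx.xyz @ R.T + t
        lig2 = cplx.subset(cplx.annotations["ligand"])
        moved = select_low_energy([lig2], rec)[0][1]
        assert moved == pytest.approx(base, abs=1e-9)

    def test_composition_mismatch_raises(self, docking_toy):
        toy = docking_toy
        rec = Selection(toy.cplx, toy.cplx.annotations["receptor"], "rec")
        lig = toy.cplx.subset(toy.cplx.annotations["ligand"])
        frag = lig.subset(np.arange(10))
        with pytest.raises(ValueError):
            select_low_energy([lig, frag], rec)

    def test_stable_tie_break(self, docking_toy):
        toy = docking_toy
        rec = Selection(toy.cplx, toy.cplx.annotations["receptor"], "rec")
        lig = toy.cplx.subset(toy.cplx.annotations["ligand"])
        ranked = select_low_energy([lig.copy(), lig.copy(), lig.copy()], rec)
        assert [i for i, _ in ranked] == [0, 1, 2]
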