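import numpy as np
import pytest

import ectofit as ef
from ectofit.density import MapThreshold
from ectofit.fitting import (MapPotential, StageSpec, _total_energy,
                             build_map_potential, relax, rmsd_trace,
                             run_protocol)
from ectofit.restraints import (assign_secondary_structure,
                                build_internal_restraints, dihedral,
                                evaluate_restraints, _residue_table,
                                _wrap_angle)


@pytest.fixture(scope="module")
def helix_case():
    """Displaced helix with the map generated from its true position."""
    truth = ef.make_helix(12)
    target = ef.synthesize_map(truth.select_all(), 4.0, 1.0)
    start = truth.copy()
    start.xyz += np.array([2.0, 1.5, 1.0])
    restraints = build_internal_restraints(start).merge(
        assign_secondary_structure(start))
    return truth, start, target, restraints


class TestMapPotential:
    def test_atom_at_global_maximum_has_zero_energy(self, bundle):
        g = ef.synthesize_map(bundle.select_all(), 4.0, 1.0)
        mp = build_map_potential(g, xi=0.5)
        peak = np.unravel_index(np.argmax(g.values), g.dims)
        pos = (g.origin + np.array(peak) * g.spacing)[None, :]
        e, grad = mp.energy_and_gradient(pos, np.ones(1))
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_subthreshold_region_flat(self, bundle):
        g = ef.synthesize_map(bundle.select_all(), 4.0, 1.0)
        mp = build_map_potential(g, xi=0.5)
        corner = (g.origin + 1.2 * g.spacing)[None, :]  # far from the bundle
        e, grad = mp.energy_and_gradient(corner, np.ones(1))
        assert e == pytest.approx(0.5, abs=1e-12)  # xi * 1
        assert np.allclose(grad, 0.0)

    def test_doubling_xi_doubles_energy_and_forces(self, bundle, rng):
        g = ef.synthesize_map(bundle.select_all(), 4.0, 1.0)
        mp1 = build_map_potential(g, xi=0.3)
        mp2 = build_map_potential(g, xi=0.6)
        pts = g.origin + rng.uniform(2, np.array(g.dims) - 3, size=(100, 3)) * g.spacing
        w = rng.uniform(0.5, 2.0, size=100)
        e1, g1 = mp1.energy_and_gradient(pts, w)
        e2, g2 = mp2.energy_and_gradient(pts, w)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)
        assert np.allclose(g2, 2 * g1, rtol=1e-12)

    def test_all_zero_map_rejected(self):
        from ectofit.density import DensityGrid
        flat = DensityGrid(np.zeros(3), 1.0, np.zeros((4, 4, 4)), 4.0)
        with pytest.raises(ValueError):
            build_map_potential(flat)

    def test_invalid_xi_rejected(self, bundle):
        g = ef.synthesize_map(bundle.select_all(), 4.0, 1.0)
        with pytest.raises(ValueError):
            MapPotential(g, xi=-1.0, threshold=MapThreshold(0.0))


class TestRelax:
    def test_empty_mobile_is_noop(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("noop", ef.Selection(start, np.array([], dtype=np.int64)),
                          [build_map_potential(target)], max_steps=50)
        res = relax(start, stage, rs)
        assert np.array_equal(res.final.xyz, start.xyz)

    def test_restraint_only_equilibrium(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("still", start.select_all(), [], max_steps=300)
        res = relax(start, stage, rs)
        assert ef.rmsd(res.final.xyz, start.xyz) < 0.1

    def test_displaced_structure_recovers_ground_truth(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("fit", start.select_all(),
                          [build_map_potential(target)], max_steps=3000)
        res = relax(start, stage, rs)
        # a blurred single helix keeps a weak axial degeneracy; the pose must
        # land essentially on top of the truth
        assert ef.rmsd(res.final.xyz, truth.xyz) < 1.0
        assert ef.ccc(res.final.select_all(), target) > 0.99

    def test_logged_energy_monotone_nonincreasing(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("fit", start.select_all(),
                          [build_map_potential(target)], max_steps=500)
        res = relax(start, stage, rs, save_every=10)
        tot = [e["total"] for e in res.energies]
        assert all(a >= b - 1e-9 for a, b in zip(tot, tot[1:]))

    def test_energy_bookkeeping_recomputable(self, helix_case):
        truth, start, target, rs = helix_case
        mp = build_map_potential(target)
        stage = StageSpec("fit", start.select_all(), [mp], max_steps=200)
        res = relax(start, stage, rs, save_every=50)
        mob = stage.mobile.indices
        w = start.mass[mob] / start.mass[mob].mean()
        for frame, logged in zip(res.frames, res.energies):
            comps, _ = _total_energy(frame, rs, [(mp, mob, w)])
            assert comps["total"] == pytest.approx(logged["total"], rel=1e-6)

    def test_step_displacement_cap(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("fit", start.select_all(),
                          [build_map_potential(target)], max_steps=60,
                          step_cap=0.2)
        res = relax(start, stage, rs, save_every=1)
        for a, b in zip(res.frames, res.frames[1:]):
            # frames are saved every step here; each step obeys the cap
            assert np.linalg.norm(b - a, axis=1).max() <= 0.2 + 1e-9

    def test_restraint_efficacy_along_trajectory(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("fit", start.select_all(),
                          [build_map_potential(target)], max_steps=1500)
        res = relax(start, stage, rs, save_every=100)
        residues = _residue_table(res.final)
        chir_sign_ref = None
        for frame in res.frames:
            for i in range(len(residues) - 1):
                a, b = residues[i]["atoms"], residues[i + 1]["atoms"]
                omega = dihedral(frame[a["CA"]], frame[a["C"]],
                                 frame[b["N"]], frame[b["CA"]])
                assert abs(np.degrees(_wrap_angle(np.array([omega - np.pi]))[0])) <= 30.0
            signs = []
            for row in residues:
                at = row["atoms"]
                signs.append(np.sign(dihedral(frame[at["N"]], frame[at["C"]],
                                              frame[at["CA"]], frame[at["CB"]])))
            if chir_sign_ref is None:
                chir_sign_ref = signs
            assert signs == chir_sign_ref


class TestProtocol:
    def test_single_stage_equals_relax(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("only", start.select_all(),
                          [build_map_potential(target)], max_steps=150)
        a = relax(start, stage, rs)
        b = run_protocol(start, [stage], rs)
        assert np.allclose(a.final.xyz, b.final.xyz)

    def test_stage_markers_and_series_lengths(self, helix_case):
        truth, start, target, rs = helix_case
        mp = build_map_potential(target)
        stages = [StageSpec("one", start.select_all(), [mp], max_steps=60),
                  StageSpec("two", start.select_all(), [mp], max_steps=60)]
        res = run_protocol(start, stages, rs, reference=truth, save_every=20)
        assert set(res.stage_labels) == {"one", "two"}
        assert len(res.rmsd_series) == len(res.frames)
        assert len(res.ccc_series) == len(res.frames)
        df = res.to_frame()
        assert {"stage", "step", "total", "ccc", "rmsd_A"} <= set(df.columns)

    def test_empty_protocol_rejected(self, helix_case):
        truth, start, target, rs = helix_case
        with pytest.raises(ValueError):
            run_protocol(start, [], rs)


class TestProtocolConfig:
    def test_load_protocol_yaml(self, tmp_path, benchmark):
        from ectofit.fitting import load_protocol

        cfg = tmp_path / "protocol.yaml"
        cfg.write_text(
            "stages:\n"
            "  - label: stage-a\n"
            "    mobile: [L1, alphaCT]\n"
            "    restrained: [hormone]\n"
            "    maps:\n"
            "      - {map: L1, selection: L1}\n"
            "      - alphaCT\n"
            "    max_steps: 40\n"
            "  - label: stage-b\n"
            "    mobile: [hormone]\n"
            "    maps: [hormone]\n"
            "    xi: 0.5\n"
        )
        stages = load_protocol(cfg, benchmark.start, benchmark.maps)
        assert [s.label for s in stages] == ["stage-a", "stage-b"]
        assert stages[0].max_steps == 40
        assert len(stages[0].active_maps) == 2
        assert isinstance(stages[0].active_maps[0], tuple)  # scoped map
        assert stages[1].active_maps[0].xi == pytest.approx(0.5)
        assert len(stages[0].positionally_restrained) == \
            len(benchmark.start.select("hormone"))


class TestRmsdTrace:
    def test_reference_equal_to_final_ends_at_zero(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("fit", start.select_all(),
                          [build_map_potential(target)], max_steps=100)
        res = relax(start, stage, rs)
        df = rmsd_trace(res, res.final, res.final.select_all())
        assert df["rmsd_A"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert df.attrs["convention"] == "direct"

    def test_uniform_shift_of_reference(self, helix_case):
        """Direct (unsuperposed) RMSD vs a shifted copy of a rigid frame is
        exactly the shift length."""
        truth, start, target, rs = helix_case
        stage = StageSpec("fit", start.select_all(), [], max_steps=5)
        res = relax(start, stage, rs)
        shifted = res.final.copy()
        t = np.array([1.0, 0.0, 0.0])
        shifted.xyz = res.final.xyz + t
        df = rmsd_trace(res, shifted, res.final.select_all())
        last = df["rmsd_A"].iloc[-1]
        assert last == pytest.approx(np.linalg.norm(t), abs=1e-9)

    def test_superposed_flag(self, helix_case):
        truth, start, target, rs = helix_case
        stage = StageSpec("fit", start.select_all(), [], max_steps=5)
        res = relax(start, stage, rs)
        rot = res.final.copy()
        theta = np.radians(30)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rot.xyz = res.final.xyz @ R.T + 5.0
        direct = rmsd_trace(res, rot, res.final.select_all())
        sup = rmsd_trace(res, rot, res.final.select_all(), superpose=True)
        assert sup["rmsd_A"].iloc[-1] <= direct["rmsd_A"].iloc[-1]
        assert sup["rmsd_A"].iloc[-1] == pytest.approx(0.0, abs=1e-6)
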