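"""Shell detection, resfile merging, restrained optimisation, packing stages."""

import numpy as np
import pytest

from enzgraft.design import (DesignConfig, PackerTask, cst_opt, cst_predock,
                             design_cycle, detect_design_shell, merge_resfile,
                             one_body_energies, pack_structure,
                             packer_background, parse_resfile,
                             repack_without_ligand, restraint_scores,
                             task_from_shell, unconstrained_repack,
                             _restrained_ligand_atoms)
from enzgraft.energy import EnergyModel
from enzgraft.structure import Atom, CatalyticAnnotation, Residue, Structure

ZERO_ENERGY = dict(w_rep=0.0, w_atr=0.0, w_hb=0.0)


def _bare_structure(entries, lig_at=(0.0, 0.0, 0.0)):
    """Residues from (number, CA, CB-or-None[, name3]) plus a 1-atom ligand."""
    residues = []
    for entry in entries:
        number, ca, cb = entry[:3]
        name3 = entry[3] if len(entry) > 3 else "ALA"
        res = Residue(name3=name3, chain="A", number=number)
        res.atoms["CA"] = Atom("CA", "C", np.asarray(ca, float))
        if cb is not None:
            res.atoms["CB"] = Atom("CB", "C", np.asarray(cb, float))
        residues.append(res)
    lig = Residue(name3="LIG", chain="X", number=1, is_ligand=True)
    lig.atoms["C1"] = Atom("C1", "C", np.asarray(lig_at, float))
    return Structure(residues=residues, ligands=[lig])


class TestShellDetection:
    cfg = DesignConfig()  # cuts 6/8/10/12

    def test_rule_i_designable(self):
        st = _bare_structure([(1, (5.0, 0, 0), (6.0, 0, 0))])
        shell = detect_design_shell(st, self.cfg)
        assert shell.of(("A", 1)) == "designable"

    def test_rule_ii_cbeta_closer(self):
        st = _bare_structure([(1, (7.0, 0, 0), (6.5, 0, 0))])
        assert detect_design_shell(st, self.cfg).of(("A", 1)) == "designable"

    def test_rule_iii_repackable(self):
        st = _bare_structure([(1, (9.0, 0, 0), (9.5, 0, 0))])
        assert detect_design_shell(st, self.cfg).of(("A", 1)) == "repackable"

    def test_far_residue_static(self):
        st = _bare_structure([(1, (13.0, 0, 0), (13.5, 0, 0))])
        assert detect_design_shell(st, self.cfg).of(("A", 1)) == "static"

    def test_glycine_falls_back_to_calpha(self):
        st = _bare_structure([(1, (7.0, 0, 0), None, "GLY")])
        assert detect_design_shell(st, self.cfg).of(("A", 1)) == "designable"

    def test_catalytic_always_repackable(self):
        st = _bare_structure([(1, (13.0, 0, 0), (13.5, 0, 0))])
        st.annotations = [CatalyticAnnotation(1, "A", 1, "ALA")]
        assert detect_design_shell(st, self.cfg).of(("A", 1)) == "catalytic"
        fixed = DesignConfig(fix_catalytic_aa=True)
        assert detect_design_shell(st, fixed).of(("A", 1)) == "static"

    def test_missing_ligand_is_error(self):
        st = _bare_structure([(1, (5.0, 0, 0), (6.0, 0, 0))])
        st.ligands = []
        with pytest.raises(ValueError, match="ligand"):
            detect_design_shell(st, self.cfg)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            entries = []
            for i in range(30):
                ca = rng.uniform(-16, 16, 3)
                cb = ca + rng.normal(size=3) * 0.9
                entries.append((i + 1, ca, cb))
            lig = rng.uniform(-2, 2, 3)
            st = _bare_structure(entries, lig_at=lig)
            shell = detect_design_shell(st, self.cfg)
            for num, ca, cb in entries:
                da = np.linalg.norm(np.asarray(ca) - lig)
                db = np.linalg.norm(np.asarray(cb) - lig)
                if da < 6.0:
                    want = "designable"
                elif da < 8.0 and db < da:
                    want = "designable"
                elif da < 10.0:
                    want = "repackable"
                elif da < 12.0 and db < da:
                    want = "repackable"
                else:
                    want = "static"
                assert shell.of(("A", num)) == want

    def test_designable_positions_exclude_cysteine(self):
        st = _bare_structure([(1, (5.0, 0, 0), (6.0, 0, 0))])
        task = task_from_shell(st, detect_design_shell(st, self.cfg))
        allowed = task.entries[("A", 1)][1]
        assert "CYS" not in allowed and len(allowed) == 19


class TestResfile:
    def test_auto_default_with_override(self):
        st = _bare_structure([(1, (5.0, 0, 0), (6.0, 0, 0)),
                              (2, (5.0, 1, 0), (6.0, 1, 0))])
        shell = detect_design_shell(st, DesignConfig())
        task = merge_resfile("AUTO\nstart\n1 A NATRO\n", shell, st)
        assert task.entries[("A", 1)] == ("static", ())
        assert task.entries[("A", 2)][0] == "designable"

    def test_no_resfile_equals_shell(self):
        st = _bare_structure([(1, (5.0, 0, 0), (6.0, 0, 0))])
        shell = detect_design_shell(st, DesignConfig())
        assert merge_resfile(None, shell, st).entries == \
            task_from_shell(st, shell).entries

    def test_pikaa_restricts_types(self):
        st = _bare_structure([(1, (5.0, 0, 0), (6.0, 0, 0))])
        shell = detect_design_shell(st, DesignConfig())
        task = merge_resfile("AUTO\nstart\n1 A PIKAA ST\n", shell, st)
        assert set(task.entries[("A", 1)][1]) == {"SER", "THR"}

    def test_absent_residue_is_error(self):
        st = _bare_structure([(1, (5.0, 0, 0), (6.0, 0, 0))])
        shell = detect_design_shell(st, DesignConfig())
        with pytest.raises(Exception):
            merge_resfile("AUTO\nstart\n99 A NATRO\n", shell, st)

    def test_header_parse(self):
        default, per = parse_resfile("NATRO\nstart\n5 A PIKAA KR\n")
        assert default == "NATRO" and per[("A", 5)] == ("PIKAA", "KR")


class TestCstOpt:
    def test_perfect_start_stays_put(self, match_model, planted):
        cfg = DesignConfig(seed=1)
        model = EnergyModel(**ZERO_ENERGY)
        before = restraint_scores(match_model, planted.theozyme,
                                  planted.ligand)[0]
        assert before == pytest.approx(0.0, abs=1e-9)
        out = cst_opt(match_model, planted.theozyme, planted.ligand, cfg,
                      model)
        after = restraint_scores(out, planted.theozyme, planted.ligand)[0]
        assert after == pytest.approx(0.0, abs=1e-9)
        move = np.max(np.abs(out.ligand.heavy_coords()
                             - match_model.ligand.heavy_coords()))
        assert move < 1e-3

    def test_perturbed_ligand_recovers(self, match_model, planted):
        cfg = DesignConfig(seed=1)
        model = EnergyModel(**ZERO_ENERGY)
        st = match_model.copy()
        for a in st.ligand.atoms.values():
            a.xyz = a.xyz + np.array([0.25, -0.1, 0.12])
        before = restraint_scores(st, planted.theozyme, planted.ligand)[0]
        assert before > 0
        out = cst_opt(st, planted.theozyme, planted.ligand, cfg, model)
        after = restraint_scores(out, planted.theozyme, planted.ligand)[0]
        assert after <= before
        assert after < 0.05 * before

    def test_static_region_is_untouched(self, match_model, planted):
        cfg = DesignConfig(seed=1)
        shell = detect_design_shell(match_model, cfg)
        out = cst_opt(match_model, planted.theozyme, planted.ligand, cfg)
        for key in shell.keys_with("static"):
            a = match_model.find(*key).heavy_coords()
            b = out.find(*key).heavy_coords()
            assert np.array_equal(a, b)

    def test_shell_mutated_to_alanine(self, match_model, planted):
        cfg = DesignConfig(seed=1)
        shell = detect_design_shell(match_model, cfg)
        out = cst_opt(match_model, planted.theozyme, planted.ligand, cfg)
        for key in shell.keys_with("designable", "repackable"):
            assert out.find(*key).name3 in ("ALA", "GLY")
        for key in shell.keys_with("catalytic"):
            assert out.find(*key).name3 == match_model.find(*key).name3


class TestCstPredock:
    def test_zero_trials_identical(self, match_model, planted):
        cfg = DesignConfig(seed=1, dock_trials=0)
        out = cst_predock(match_model, planted.theozyme, planted.ligand, cfg)
        assert np.array_equal(out.ligand.heavy_coords(),
                              match_model.ligand.heavy_coords())

    def test_pure_rotation_fixes_restrained_centroid(self, match_model,
                                                     planted):
        cfg = DesignConfig(seed=5, dock_trials=15, trans_magnitude=0.0,
                           rot_magnitude=8.0)
        names = _restrained_ligand_atoms(planted.theozyme, planted.ligand)
        before = np.mean([match_model.ligand.coord(n) for n in names], axis=0)
        out = cst_predock(match_model, planted.theozyme, planted.ligand, cfg)
        after = np.mean([out.ligand.coord(n) for n in names], axis=0)
        assert np.linalg.norm(after - before) < 1e-9

    def test_seed_determinism(self, match_model, planted):
        cfg = DesignConfig(seed=5, dock_trials=20)
        a = cst_predock(match_model, planted.theozyme, planted.ligand, cfg)
        b = cst_predock(match_model, planted.theozyme, planted.ligand, cfg)
        assert np.array_equal(a.ligand.heavy_coords(),
                              b.ligand.heavy_coords())
        cfg2 = DesignConfig(seed=6, dock_trials=20)
        c = cst_predock(match_model, planted.theozyme, planted.ligand, cfg2)
        assert not np.array_equal(a.ligand.heavy_coords(),
                                  c.ligand.heavy_coords())


class TestPacker:
    def test_huge_native_bonus_freezes_sequence(self, match_model, planted):
        cfg = DesignConfig(seed=2, native_bonus=1e6)
        shell = detect_design_shell(match_model, cfg)
        task = task_from_shell(match_model, shell)
        out = pack_structure(match_model, task, cfg, EnergyModel(),
                             planted.theozyme, planted.ligand)
        assert [r.name3 for r in out.residues] == \
            [r.name3 for r in match_model.residues]

    def test_lig_weight_scales_ligand_term_exactly(self, match_model, planted):
        cfg = DesignConfig(seed=2)
        shell = detect_design_shell(match_model, cfg)
        task = task_from_shell(match_model, shell)
        bg, lig_arrays = packer_background(match_model, task)
        key = [k for k in task.movable()
               if task.entries[k][0] == "designable"][0]
        base = one_body_energies(match_model, key, task, cfg, EnergyModel(),
                                 bg, lig_arrays, 1.6, {}, planted.ligand)
        doubled = one_body_energies(match_model, key, task, cfg, EnergyModel(),
                                    bg, lig_arrays, 3.2, {}, planted.ligand)
        for a, b in zip(base, doubled):
            assert b.one_body - a.one_body == pytest.approx(
                1.6 * a.one_body_lig, abs=1e-9)

    def test_no_designable_positions_keeps_sequence(self, match_model,
                                                    planted):
        cfg = DesignConfig(seed=2)
        shell = detect_design_shell(match_model, cfg)
        task = task_from_shell(match_model, shell)
        repack_only = PackerTask(entries={
            k: (("repackable", (match_model.find(*k).name3,))
                if mode in ("designable", "repackable", "catalytic")
                else (mode, allowed))
            for k, (mode, allowed) in task.entries.items()})
        out = pack_structure(match_model, repack_only, cfg, EnergyModel(),
                             planted.theozyme, planted.ligand)
        assert [r.name3 for r in out.residues] == \
            [r.name3 for r in match_model.residues]


class TestFinalStages:
    def test_no_unconstrained_repack_flag(self, match_model, planted):
        cfg = DesignConfig(seed=2, no_unconstrained_repack=True)
        out, weights = unconstrained_repack(match_model, planted.theozyme,
                                            planted.ligand, cfg)
        assert weights["cst"] == 0.0
        for a, b in zip(match_model.residues, out.residues):
            assert a.name3 == b.name3
            assert np.array_equal(a.heavy_coords(), b.heavy_coords())

    def test_restraint_weight_zero_in_stage_log(self, match_model, planted):
        cfg = DesignConfig(seed=2, cst_min=False)
        _, weights = unconstrained_repack(match_model, planted.theozyme,
                                          planted.ligand, cfg)
        assert weights == {"cst": 0.0}

    def test_apo_rmsd_zero_for_single_rotamer_choice(self, match_model,
                                                     planted):
        # alanine has a single conformation: the apo repack cannot move it
        from enzgraft.structure import build_side_chain
        st = match_model.copy()
        for ann in st.annotations:
            res = st.find(ann.chain, ann.number)
            ala = build_side_chain(res, "ALA", [])
            res.name3, res.atoms = "ALA", ala.atoms
            ann.name3 = "ALA"
        st.reindex()
        cfg = DesignConfig(seed=2)
        _, rmsds, mean = repack_without_ligand(st, planted.theozyme,
                                               planted.ligand, cfg)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in rmsds.values())
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_chi_flip_rmsd_matches_analytic_value(self, scaffold):
        """A 120-degree chi1 flip of Ser displaces OG by 2 r sin(60)."""
        from enzgraft.chem import RESIDUE_TOPOLOGIES
        from enzgraft.structure import build_side_chain, side_chain_rmsd
        res = scaffold.residues[4]
        a = build_side_chain(res, "SER", [60.0])
        b = build_side_chain(res, "SER", [-60.0])
        # radius of OG about the CA-CB rotation axis
        axis = a.coord("CB") - a.coord("CA")
        axis /= np.linalg.norm(axis)
        v = a.coord("OG") - a.coord("CB")
        r = np.linalg.norm(v - np.dot(v, axis) * axis)
        d = 2.0 * r * np.sin(np.radians(60.0))
        # shared side-chain atoms are CB (identical) and OG
        expected = np.sqrt(d ** 2 / 2.0)
        assert side_chain_rmsd(a, b) == pytest.approx(expected, abs=1e-9)
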