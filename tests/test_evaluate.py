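"""Design metrics, scorefile round trip, and cutoff filtering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from enzgraft.cst import Theozyme
from enzgraft.design import DesignConfig, restraint_scores
from enzgraft.energy import EnergyModel
from enzgraft.evaluate import (CutoffSpec, ScoreRecord, compute_score_record,
                               count_buried_unsat, count_hbonds,
                               count_nonlocal_contacts, filter_designs,
                               interface_score, packing_metric, parse_cutoffs,
                               read_scorefile, score_reference,
                               write_scorefile)
from enzgraft.geometry import place_atom
from enzgraft.structure import Atom, Residue, Structure


def _residue(number, atoms, chain="A", name3="ALA", is_ligand=False):
    res = Residue(name3=name3, chain=chain, number=number, is_ligand=is_ligand)
    for name, element, xyz, flags in atoms:
        res.atoms[name] = Atom(name, element, np.asarray(xyz, float),
                               donor="D" in flags, acceptor="A" in flags)
    return res


class TestHbonds:
    def _pair(self, dist=2.9, ang=165.0):
        donor = _residue(1, [("CB", "C", (-1.43, 0, 0), ""),
                             ("OG", "O", (0, 0, 0), "DA")], name3="SER")
        acc_xyz = place_atom((0, 1, 0), (-1.43, 0, 0), (0, 0, 0),
                             dist, ang, 0.0)
        acceptor = _residue(5, [("C", "C", acc_xyz + (1.0, 0.6, 0), ""),
                                ("O", "O", acc_xyz, "A")])
        return Structure(residues=[donor, acceptor])

    def test_ideal_pair_counts_once(self):
        assert count_hbonds(self._pair()) == (1, 0)

    def test_apolar_fixture_counts_zero(self):
        a = _residue(1, [("CB", "C", (0, 0, 0), "")])
        b = _residue(2, [("CB", "C", (3.0, 0, 0), "")])
        assert count_hbonds(Structure(residues=[a, b])) == (0, 0)

    def test_long_or_bent_geometry_rejected(self):
        assert count_hbonds(self._pair(dist=3.6)) == (0, 0)
        assert count_hbonds(self._pair(ang=100.0)) == (0, 0)

    def test_invariant_under_rigid_motion(self):
        st = self._pair()
        R = Rotation.random(random_state=2).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        for res in st.residues:
            for a in res.atoms.values():
                a.xyz = R @ a.xyz + t
        assert count_hbonds(st) == (1, 0)


class TestBuriedUnsat:
    def _buried(self, with_donor=False):
        residues = [_residue(1, [("C", "C", (0.4, 0.3, 0), ""),
                                 ("O", "O", (0, 0, 0), "A")])]
        rng = np.random.default_rng(3)
        number = 10
        shell = []
        # 14 apolar neighbours within burial range of the carbonyl oxygen
        for k in range(14):
            v = rng.normal(size=3)
            v = 4.0 * v / np.linalg.norm(v)
            shell.append(("CB", "C", v, ""))
            residues.append(_residue(number, [shell[-1]]))
            number += 1
        if with_donor:
            # base anti to the acceptor so the donor-direction test passes
            residues.append(_residue(50, [
                ("CB", "C", (0, 0, 2.9 + 1.43), ""),
                ("OG", "O", (0, 0, 2.9), "D")], name3="SER"))
        return Structure(residues=residues)

    def test_buried_unsatisfied_oxygen_counted(self):
        total, cat = self._buried().count if False else \
            count_buried_unsat(self._buried())
        assert total >= 1

    def test_exposed_polar_atom_not_counted(self):
        st = Structure(residues=[_residue(1, [("C", "C", (1.2, 0, 0), ""),
                                              ("O", "O", (0, 0, 0), "A")])])
        assert count_buried_unsat(st)[0] == 0

    def test_adding_donor_decrements_by_one(self):
        before = count_buried_unsat(self._buried(with_donor=False))[0]
        after = count_buried_unsat(self._buried(with_donor=True))[0]
        assert before - after == 1


class TestNonlocalContacts:
    def test_extended_chain_has_none(self):
        residues = [_residue(i + 1, [("CA", "C", (3.5 * i, 0, 0), "")])
                    for i in range(12)]
        assert count_nonlocal_contacts(Structure(residues=residues)) == (0, 0)

    def test_single_long_range_pair(self):
        residues = [
            _residue(1, [("CA", "C", (0, 0, 0), "")]),
            _residue(3, [("CA", "C", (40, 0, 0), "")]),
            _residue(20, [("CA", "C", (4.0, 0, 0), "")]),
        ]
        assert count_nonlocal_contacts(Structure(residues=residues))[0] == 1

    def test_sequence_local_pair_ignored(self):
        residues = [
            _residue(1, [("CA", "C", (0, 0, 0), "")]),
            _residue(5, [("CA", "C", (4.0, 0, 0), "")]),
        ]
        assert count_nonlocal_contacts(Structure(residues=residues))[0] == 0


class TestPacking:
    def test_isolated_atom_scores_zero(self):
        st = Structure(residues=[_residue(1, [("CA", "C", (0, 0, 0), "")])])
        assert packing_metric(st) == 0.0

    def test_deleting_an_atom_lowers_packing(self):
        rng = np.random.default_rng(4)
        atoms = [("CA", "C", 3.8 * v / np.linalg.norm(v), "")
                 for v in rng.normal(size=(14, 3))]
        atoms.append(("CA", "C", (0, 0, 0), ""))
        full = Structure(residues=[_residue(i + 1, [a])
                                   for i, a in enumerate(atoms)])
        reduced = Structure(residues=[_residue(i + 1, [a])
                                      for i, a in enumerate(atoms[1:])])
        assert packing_metric(full) > packing_metric(reduced)

    def test_bounded_in_unit_interval(self, match_model):
        for with_lig in (True, False):
            v = packing_metric(match_model, with_ligand=with_lig)
            assert 0.0 <= v <= 1.0


class TestInterface:
    def test_distant_ligand_scores_zero(self, match_model):
        st = match_model.copy()
        for a in st.ligand.atoms.values():
            a.xyz = a.xyz + np.array([50.0, 0, 0])
        assert interface_score(st) == 0.0

    def test_decomposition_identity(self, match_model):
        model = EnergyModel()
        complex_e = model.structure_energy(match_model)["total"]
        prot = match_model.copy()
        prot.ligands = []
        lig_only = match_model.copy()
        lig_only.residues = []
        lig_only.reindex()
        expected = complex_e \
            - model.structure_energy(prot)["total"] \
            - model.structure_energy(lig_only)["total"]
        assert interface_score(match_model, model) == \
            pytest.approx(expected, abs=1e-9)

    def test_deterministic(self, match_model):
        assert interface_score(match_model) == interface_score(match_model)


class TestScorefile:
    def _records(self, n):
        rng = np.random.default_rng(9)
        out = []
        for i in range(n):
            metrics = {"total_score": float(rng.normal()),
                       "all_cst": float(abs(rng.normal())),
                       "SR1": 0.0, "tot_pstat_pm": float(rng.uniform())}
            metrics["SR1"] = metrics["all_cst"]
            metrics["SR2"] = metrics["all_cst"]
            out.append(ScoreRecord(design_id=f"d{i}", metrics=metrics))
        return out

    def test_line_count(self, tmp_path):
        path = tmp_path / "scores.sc"
        write_scorefile(self._records(3), path)
        assert len(path.read_text().strip().splitlines()) == 4

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "scores.sc"
        records = self._records(4)
        write_scorefile(records, path)
        back = read_scorefile(path)
        assert [r.design_id for r in back] == [r.design_id for r in records]
        for a, b in zip(records, back):
            for k, v in a.metrics.items():
                assert b.metrics[k] == pytest.approx(v, abs=1e-3)

    def test_single_catalytic_residue_ligand_is_sr2(self, match_model,
                                                    planted):
        st = match_model.copy()
        st.annotations = [a for a in st.annotations if a.block_index == 1]
        tz1 = Theozyme(blocks=[planted.theozyme.blocks[0]],
                       ligand_name=planted.theozyme.ligand_name)
        rec = compute_score_record(st, tz1, planted.ligand)
        assert "SR2" in rec.metrics and "SR3" not in rec.metrics
        assert rec.metrics["SR2"] == rec.metrics["SR1"]  # one ligand block

    def test_mismatched_columns_rejected(self, tmp_path):
        records = self._records(2)
        records[1].metrics["extra"] = 1.0
        with pytest.raises(ValueError, match="column"):
            write_scorefile(records, tmp_path / "x.sc")


class TestFilter:
    def test_example_cutoff(self):
        rec = ScoreRecord("d", {"all_cst": 5.0})
        passing, counts = filter_designs([rec],
                                         [CutoffSpec("all_cst", "<", 6.5)])
        assert passing == [rec] and counts["all_cst < 6.5"] == 1

    def test_empty_records(self):
        assert filter_designs([], [CutoffSpec("all_cst", "<", 6.5)])[0] == []

    def test_no_cutoffs_passes_everything(self):
        recs = [ScoreRecord(f"d{i}", {"m": float(i)}) for i in range(5)]
        assert filter_designs(recs, [])[0] == recs

    def test_counts_match_bruteforce(self):
        rng = np.random.default_rng(21)
        recs = [ScoreRecord(f"d{i}", {"a": float(rng.normal()),
                                      "b": float(rng.normal())})
                for i in range(10)]
        cutoffs = [CutoffSpec("a", "<", 0.0), CutoffSpec("b", ">", -0.5)]
        passing, counts = filter_designs(recs, cutoffs)
        brute_a = sum(1 for r in recs if r.metrics["a"] < 0.0)
        brute_b = sum(1 for r in recs if r.metrics["b"] > -0.5)
        brute_all = [r for r in recs
                     if r.metrics["a"] < 0.0 and r.metrics["b"] > -0.5]
        assert counts["a < 0"] == brute_a
        assert counts["b > -0.5"] == brute_b
        assert passing == brute_all

    def test_unknown_metric_raises(self):
        rec = ScoreRecord("d", {"a": 1.0})
        with pytest.raises(KeyError):
            filter_designs([rec], [CutoffSpec("zz", "<", 1.0)])

    def test_parse_cutoffs(self):
        cuts = parse_cutoffs("all_cst < 6.5\n# comment\ntot_pstat_pm > -0.05\n")
        assert [(c.metric, c.comparator, c.threshold) for c in cuts] == \
            [("all_cst", "<", 6.5), ("tot_pstat_pm", ">", -0.05)]


class TestScoreReference:
    def test_planted_reference_holds_restraints(self, match_model, planted):
        model = EnergyModel(w_rep=0.0, w_atr=0.0, w_hb=0.0)
        rec = score_reference(match_model, planted.theozyme, planted.ligand,
                              DesignConfig(seed=4), model)
        assert rec.metrics["all_cst"] == pytest.approx(0.0, abs=1e-6)

    def test_deterministic_under_seed(self, match_model, planted):
        model = EnergyModel(w_rep=0.0, w_atr=0.0, w_hb=0.0)
        a = score_reference(match_model, planted.theozyme, planted.ligand,
                            DesignConfig(seed=4), model)
        b = score_reference(match_model, planted.theozyme, planted.ligand,
                            DesignConfig(seed=4), model)
        assert a.metrics == b.metrics

    def test_all_cst_self_consistency(self, match_model, planted):
        rec = compute_score_record(match_model, planted.theozyme,
                                   planted.ligand)
        independent, per_block = restraint_scores(
            match_model, planted.theozyme, planted.ligand)
        assert rec.metrics["all_cst"] == pytest.approx(independent, abs=1e-9)
        n = len(planted.theozyme.blocks)
        assert sum(rec.metrics[f"SR{i}"] for i in range(1, n + 1)) == \
            pytest.approx(rec.metrics["all_cst"], abs=1e-9)

    def test_metrics_invariant_under_rigid_motion(self, match_model, planted):
        rec0 = compute_score_record(match_model, planted.theozyme,
                                    planted.ligand)
        st = match_model.copy()
        R = Rotation.random(random_state=8).as_matrix()
        t = np.array([7.0, -4.0, 2.0])
        for res in list(st.residues) + list(st.ligands):
            for a in res.atoms.values():
                a.xyz = R @ a.xyz + t
        st.reindex()
        rec1 = compute_score_record(st, planted.theozyme, planted.ligand)
        for k in rec0.metrics:
            assert rec1.metrics[k] == pytest.approx(rec0.metrics[k], abs=1e-6)
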