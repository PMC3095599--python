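"""Rotamer building, classic/secondary matching, 6D hashing, match extraction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from enzgraft import fixtures as fx
from enzgraft.cst import resolve_atom_triples
from enzgraft.chem import RESIDUE_TOPOLOGIES
from enzgraft.geometry import Pose6D, block_score, pose_from_frame_triple
from enzgraft.matcher import (Hit, MatchConfig, Rotamer, bin_key,
                              build_rotamers, classic_match_interaction,
                              find_matches, hash_hits, ligand_frame_atoms,
                              run_matcher, secondary_match_interaction)


class TestRotamers:
    def test_two_chi_residue_gives_nine(self, scaffold):
        rots = build_rotamers(scaffold, scaffold.residues[2].key, ["ASP"])
        assert len(rots) == 9
        assert {r.residue_type for r in rots} == {"ASP"}

    def test_ex1_triples_chi1_samples(self, scaffold):
        rots = build_rotamers(scaffold, scaffold.residues[2].key, ["ASP"],
                              ex1=True)
        assert len(rots) == 27

    def test_glycine_contributes_no_rotamers(self, scaffold):
        assert build_rotamers(scaffold, scaffold.residues[2].key, ["GLY"]) == []

    def test_use_input_appends_native(self, scaffold):
        st = scaffold.copy()
        from enzgraft.structure import build_side_chain
        res = st.residues[2]
        native = build_side_chain(res, "SER", [37.0])
        res.name3, res.atoms = "SER", native.atoms
        st.reindex()
        rots = build_rotamers(st, res.key, ["SER"], use_input=True)
        assert len(rots) == 4
        assert rots[-1].chi == pytest.approx((37.0,), abs=1e-6)

    def test_rotamer_atoms_match_chi(self, scaffold):
        from enzgraft.geometry import periodic_delta
        from enzgraft.structure import measure_chis
        rots = build_rotamers(scaffold, scaffold.residues[2].key, ["LYS"])
        r = rots[13]
        for measured, wanted in zip(measure_chis(r.residue), r.chi):
            assert float(periodic_delta(measured, wanted, 360.0)) < 1e-6


class TestClassic:
    def test_planted_site_yields_zero_score_hit(self, planted):
        block = planted.theozyme.blocks[0]
        cfg = MatchConfig()
        frame = ligand_frame_atoms(planted.theozyme, planted.ligand, cfg)
        hits = classic_match_interaction(
            planted.scaffold, block, 1, [planted.truth[0].position],
            planted.ligand, cfg, frame)
        assert hits
        assert min(h.score for h in hits) == 0.0

    def test_no_positions_no_hits(self, planted):
        cfg = MatchConfig()
        frame = ligand_frame_atoms(planted.theozyme, planted.ligand, cfg)
        assert classic_match_interaction(
            planted.scaffold, planted.theozyme.blocks[0], 1, [],
            planted.ligand, cfg, frame) == []

    def test_occluding_wall_rejects_everything(self, planted):
        """A dense backbone cage around the position leaves no free placement."""
        from enzgraft.structure import Atom, Residue
        caged = planted.scaffold.copy()
        position = planted.truth[0].position
        center = caged.find(*position).coord("CB")
        number = 900
        grid = np.arange(-14.0, 14.1, 2.0)
        for x in grid:
            for y in grid:
                for z in grid:
                    p = center + np.array([x, y, z])
                    if np.linalg.norm(p - center) > 14.0:
                        continue
                    res = Residue(name3="ALA", chain="W", number=number)
                    res.atoms["CA"] = Atom("CA", "C", p)
                    caged.residues.append(res)
                    number += 1
        caged.reindex()
        diag = {}
        cfg = MatchConfig()
        frame = ligand_frame_atoms(planted.theozyme, planted.ligand, cfg)
        hits = classic_match_interaction(
            caged, planted.theozyme.blocks[0], 1, [position],
            planted.ligand, cfg, frame, diagnostics=diag)
        assert hits == []
        assert diag["classic_1_rejected"] > 0

    def test_hit_count_invariant_under_rigid_motion(self, planted):
        block = planted.theozyme.blocks[0]
        cfg = MatchConfig()
        frame = ligand_frame_atoms(planted.theozyme, planted.ligand, cfg)
        positions = [planted.truth[0].position]
        n0 = len(classic_match_interaction(
            planted.scaffold, block, 1, positions, planted.ligand, cfg, frame))
        moved = planted.scaffold.copy()
        R = Rotation.from_euler("xyz", [20, -35, 160], degrees=True).as_matrix()
        t = np.array([4.0, -3.0, 9.0])
        for res in moved.residues:
            for a in res.atoms.values():
                a.xyz = R @ a.xyz + t
        moved.reindex()
        n1 = len(classic_match_interaction(
            moved, block, 1, positions, planted.ligand, cfg, frame))
        assert n0 == n1


class TestSecondary:
    def test_no_prior_hits_is_empty(self, planted):
        cfg = MatchConfig()
        assert secondary_match_interaction(
            planted.scaffold, planted.theozyme.blocks[2], 3, [],
            fx.pocket_positions(planted.scaffold), planted.ligand, cfg) == []

    def _truth_hit(self, planted):
        cfg = MatchConfig()
        frame = ligand_frame_atoms(planted.theozyme, planted.ligand, cfg)
        lig_names = tuple(planted.ligand.atom_names())
        lig_xyz = np.stack([planted.ligand_coords[n] for n in lig_names])
        pose = pose_from_frame_triple(
            np.stack([planted.ligand_coords[n] for n in frame]))
        t0 = planted.truth[0]
        rot = Rotamer(t0.position, t0.residue_type, t0.chi,
                      planted.truth_residue(1).coords_dict(),
                      planted.scaffold.find(*t0.position))
        return Hit(1, rot, pose, 0, lig_names, lig_xyz, 0.0)

    def test_truth_rotamer_accepted_with_same_bin(self, planted):
        cfg = MatchConfig()
        prior = [self._truth_hit(planted)]
        t3 = planted.truth[2]
        hits = secondary_match_interaction(
            planted.scaffold, planted.theozyme.blocks[2], 3, prior,
            [t3.position], planted.ligand, cfg)
        assert hits
        assert any(h.rotamer.chi == pytest.approx(t3.chi) for h in hits)
        assert all(bin_key(h.pose, cfg) == bin_key(prior[0].pose, cfg)
                   for h in hits)

    def test_undefined_parameters_are_ignored(self, planted):
        # block 3 leaves torsion_AB/torsion_B undefined: any value accepted
        block = planted.theozyme.blocks[2]
        assert "torsion_AB" not in block.params
        cfg = MatchConfig()
        prior = [self._truth_hit(planted)]
        t3 = planted.truth[2]
        hits = secondary_match_interaction(
            planted.scaffold, block, 3, prior, [t3.position],
            planted.ligand, cfg)
        accepted_chis = {h.rotamer.chi for h in hits}
        assert tuple(t3.chi) in accepted_chis

    def test_acceptance_equals_zero_block_score(self, planted):
        """Secondary acceptance is equivalent to a zero flat-bottom penalty."""
        block = planted.theozyme.blocks[2]
        cfg = MatchConfig()
        prior = [self._truth_hit(planted)]
        positions = fx.pocket_positions(planted.scaffold)[:4]
        hits = secondary_match_interaction(
            planted.scaffold, block, 3, prior, positions, planted.ligand, cfg)
        accepted = {(h.rotamer.position, h.rotamer.chi) for h in hits}
        t_lig = resolve_atom_triples(block.ligand_map, planted.ligand)
        for position in positions:
            for rot in build_rotamers(planted.scaffold, position, ["LYS"]):
                t_prot = resolve_atom_triples(
                    block.protein_map, RESIDUE_TOPOLOGIES["LYS"])
                s, _ = block_score(block, prior[0].ligand_coords, rot.coords,
                                   t_lig, t_prot)
                assert ((position, rot.chi) in accepted) == (s == 0.0)


class TestHashing:
    cfg = MatchConfig(euclid_bin=1.0, euler_bin=15.0)

    def _hit(self, pose):
        rot = Rotamer(("A", 1), "ASP", (60.0, 60.0), {}, None)
        return Hit(1, rot, pose, 0, (), np.zeros((0, 3)))

    def test_identical_poses_share_key(self):
        p = Pose6D(1.2, -0.4, 3.3, 10.0, 170.0, 300.0)
        assert bin_key(p, self.cfg) == bin_key(Pose6D(*p.as_array()), self.cfg)

    def test_offset_by_one_and_a_half_bins_differs(self):
        a = Pose6D(0.2, 0.0, 0.0, 0.0, 90.0, 0.0)
        b = Pose6D(0.2 + 1.5, 0.0, 0.0, 0.0, 90.0, 0.0)
        assert bin_key(a, self.cfg)[0] != bin_key(b, self.cfg)[0]

    def test_euler_wraparound_is_not_merged(self):
        a = Pose6D(0.0, 0.0, 0.0, 359.9, 90.0, 0.0)
        b = Pose6D(0.0, 0.0, 0.0, 0.1, 90.0, 0.0)
        assert bin_key(a, self.cfg) != bin_key(b, self.cfg)

    def test_hash_groups_by_interaction(self):
        p = Pose6D(0.0, 0.0, 0.0, 10.0, 90.0, 10.0)
        hits = [self._hit(p), self._hit(p)]
        hits[1].interaction_index = 2
        table = hash_hits(hits, self.cfg)
        assert len(table) == 1
        (key, by_int), = table.items()
        assert set(by_int) == {1, 2}


class TestFindMatches:
    cfg = MatchConfig()

    def _hit(self, i, position):
        rot = Rotamer(position, "ASP", (60.0, 60.0), {}, None)
        pose = Pose6D(0.0, 0.0, 0.0, 10.0, 90.0, 10.0)
        return Hit(i, rot, pose, 0, (), np.zeros((0, 3)))

    def test_full_bin_yields_match(self):
        hits = [self._hit(1, ("A", 1)), self._hit(2, ("A", 2)),
                self._hit(3, ("A", 3))]
        table = hash_hits(hits, self.cfg)
        assert len(find_matches(table, 3, self.cfg)) == 1

    def test_incomplete_bin_yields_none(self):
        hits = [self._hit(1, ("A", 1)), self._hit(2, ("A", 2))]
        table = hash_hits(hits, self.cfg)
        assert find_matches(table, 3, self.cfg) == []

    def test_cartesian_combination_count(self):
        hits = [self._hit(1, ("A", 1)), self._hit(1, ("A", 9)),
                self._hit(2, ("A", 2)), self._hit(3, ("A", 3))]
        table = hash_hits(hits, self.cfg)
        assert len(find_matches(table, 3, self.cfg)) == 2

    def test_shared_position_discarded(self):
        hits = [self._hit(1, ("A", 1)), self._hit(2, ("A", 1)),
                self._hit(3, ("A", 3))]
        table = hash_hits(hits, self.cfg)
        assert find_matches(table, 3, self.cfg) == []


class TestRunMatcher:
    def test_recovers_planted_truth(self, planted, planted_matches):
        matches, diag = planted_matches
        cfg = MatchConfig()
        frame = ligand_frame_atoms(planted.theozyme, planted.ligand, cfg)
        truth_pose = pose_from_frame_triple(
            np.stack([planted.ligand_coords[n] for n in frame]))
        truth_bin = bin_key(truth_pose, cfg)
        truth_pos = {t.position for t in planted.truth}
        assert any(set(m.positions) == truth_pos and m.bin == truth_bin
                   for m in matches)

    def test_best_match_score_is_zero(self, planted_matches):
        matches, _ = planted_matches
        assert matches[0].match_score == pytest.approx(0.0, abs=1e-9)

    def test_first_block_secondary_is_config_error(self, planted):
        tz = fx.make_theozyme_tim()[0]
        tz.blocks[0].algorithm = "secondary"
        with pytest.raises(ValueError, match="first theozyme interaction"):
            run_matcher(planted.scaffold, tz, planted.positions,
                        planted.ligand)

    def test_empty_posfile_clean_zero_matches(self, planted):
        matches, diag = run_matcher(planted.scaffold, planted.theozyme, [],
                                    planted.ligand)
        assert matches == [] and diag["positions"] == 0

    def test_every_hit_rescores_within_tolerance(self, planted,
                                                 planted_matches):
        """Matcher-scorer equivalence on the hits of the recovered matches."""
        matches, _ = planted_matches
        tz, lig = planted.theozyme, planted.ligand
        for m in matches:
            for h in m.hits:
                block = tz.blocks[h.interaction_index - 1]
                t_lig = resolve_atom_triples(block.ligand_map, lig)
                t_prot = resolve_atom_triples(
                    block.protein_map,
                    RESIDUE_TOPOLOGIES[h.rotamer.residue_type])
                s, _ = block_score(block, h.ligand_coords, h.rotamer.coords,
                                   t_lig, t_prot)
                assert s <= 1e-9
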