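"""Design the shell around a matched site under catalytic restraints.

Starting from a recovered match, the protocol mutates the shell to alanine
and optimises the catalytic geometry (cst_opt), then alternates sequence
design and minimisation with the protein-ligand interaction upweighted by
1.6 and a 0.8-unit bonus for keeping the native identity, and finally
repacks without restraints to ask whether the designed sequence holds the
site on its own.
"""

from enzgraft import fixtures
from enzgraft.design import DesignConfig, restraint_scores, run_design
from enzgraft.matcher import match_structure, run_matcher

scaffold = fixtures.make_toy_scaffold(seed=1)
site = fixtures.plant_site(scaffold, seed=1)
matches, _ = run_matcher(site.scaffold, site.theozyme, site.positions,
                         site.ligand)
model = match_structure(matches[0], site.scaffold, site.ligand)

cfg = DesignConfig(seed=3, design_min_cycles=1,
                   final_repack_without_ligand=True)
result = run_design(model, site.theozyme, site.ligand, cfg)
designed = result["structure"]

mutations = [(a.number, a.name3, b.name3)
             for a, b in zip(model.residues, designed.residues)
             if a.name3 != b.name3]
print("restraint score per stage (restraints are on through design and off")
print("in the final unconstrained repack; a large final value means the")
print("designed shell does not hold the site on its own):")
for stage, value in result["restraint_trace"].items():
    print(f"  {stage:<14} {value:10.2f}")
print(f"mutations introduced: {len(mutations)}")
for num, old, new in mutations:
    print(f"  {old}{num}{new}")
print("apo-repack RMSD per catalytic residue (preorganisation; small = the")
print("designed pocket holds the catalytic geometry without the ligand):")
for bi, rmsd in result["apo_rmsds"].items():
    print(f"  interaction {bi}: {rmsd:.2f} A")
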