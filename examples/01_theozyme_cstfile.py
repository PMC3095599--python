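"""Parse a theozyme constraint file and inspect its sampling behaviour.

A theozyme block relates an atom triple on the ligand to an atom triple on a
catalytic residue through six internal coordinates (one distance, two
angles, three dihedrals).  The classic matcher samples 2n+1 values across
each parameter's tolerance window, around every periodic copy of the ideal
value, and attempts the Cartesian product of all samples as ligand
placements for every rotamer it builds.
"""

from enzgraft.cst import enumerate_samples, parse_cstfile, placement_count

BLOCK = """
CST::BEGIN
  TEMPLATE::   ATOM_MAP: 1 atom_name: C1 C2 O2
  TEMPLATE::   ATOM_MAP: 1 residue3: 1n1
  TEMPLATE::   ATOM_MAP: 2 atom_type: OOC,
  TEMPLATE::   ATOM_MAP: 2 residue1: ED
  CONSTRAINT:: distanceAB:    3.06   0.2  100.  0    0
  CONSTRAINT:: angle_A:      73.60  10.0   80.0 360. 1
  CONSTRAINT:: angle_B:     120.00  15.0   80.0 360. 1
  CONSTRAINT:: torsion_A:  -101.20  15.0   60.0 360. 1
  CONSTRAINT:: torsion_AB:  180.00  90.0    0.00 360. 3
  CONSTRAINT:: torsion_B:   180.00  15.0    0.00 360. 1
CST::END
"""

theozyme = parse_cstfile(BLOCK)
theozyme.validate()
block = theozyme.blocks[0]

print(f"ligand: {theozyme.ligand_name}; catalytic partner may be any of "
      f"{', '.join(block.map2.allowed_residues)} (carboxylate-O by type)")
for name, param in block.params.items():
    values = enumerate_samples(param)
    shown = ", ".join(f"{v:g}" for v in values[:7])
    print(f"  {name:<11} x0={param.x0:<8g} n={param.n_samples}  "
          f"-> {len(values)} samples: {shown}")
print(f"ligand placements attempted per rotamer: {placement_count(block)}")
print("(the product of the per-parameter sample counts: 1*3*3*3*7*3)")
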